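"""Genomic data model: SNV/CNV panels, QC, and marker-to-region mapping.

Coordinates are 1-based closed intervals throughout; BED input is converted
from 0-based half-open on read.  SNV genotypes are minor-allele counts
(0/1/2, NaN for missing) with the minor allele re-determined from the sample
allele frequency, never taken from file REF/ALT.  CNV segment status is
dichotomous: 1 = copy-number gain or loss, 0 = unchanged.

The central product is the combined per-region marker matrix: the n x q1
SNV genotype block concatenated with the n x q2 CNV status block, analyzed
jointly downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SnvPanel",
    "CnvPanel",
    "GeneAnnotation",
    "CombinedGeneMatrix",
    "read_snv_panel",
    "read_cnv_panel",
    "read_gene_annotations",
    "write_snv_panel",
    "write_cnv_panel",
    "hwe_exact_pvalue",
    "qc_snv",
    "impute_missing",
    "build_gene_matrix",
    "build_window_matrices",
]

MISSING_TOKENS = {".", "", "NA", "NaN", "nan", "-9"}


class DataFormatError(ValueError):
    """Malformed or structurally inconsistent input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A named genomic unit on one chromosome, 1-based closed interval."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SnvPanel:
    """SNV genotypes for n samples x q1 markers (minor-allele dosage)."""

    sample_ids: list[str]
    marker_ids: list[str]
    chromosomes: list[str]
    positions: np.ndarray  # int, 1-based bp
    genotypes: np.ndarray  # float (n, q1); values 0/1/2 or NaN; imputation may
    # leave non-integer dosages

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n, q1 = self.genotypes.shape
        if n != len(self.sample_ids):
            raise DataFormatError(
                f"genotype rows ({n}) != sample count ({len(self.sample_ids)})"
            )
        if q1 != len(self.marker_ids) or q1 != len(self.chromosomes) or q1 != self.positions.size:
            raise DataFormatError("marker metadata length mismatch")
        obs = self.genotypes[~np.isnan(self.genotypes)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise DataFormatError("genotype values outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def subset_markers(self, idx: np.ndarray) -> "SnvPanel":
        idx = np.asarray(idx)
        return SnvPanel(
            sample_ids=self.sample_ids,
            marker_ids=[self.marker_ids[i] for i in idx],
            chromosomes=[self.chromosomes[i] for i in idx],
            positions=self.positions[idx],
            genotypes=self.genotypes[:, idx],
        )

    def subset_samples(self, rows: np.ndarray) -> "SnvPanel":
        rows = np.asarray(rows)
        return SnvPanel(
            sample_ids=[self.sample_ids[i] for i in rows],
            marker_ids=self.marker_ids,
            chromosomes=self.chromosomes,
            positions=self.positions,
            genotypes=self.genotypes[rows, :],
        )


@dataclass
class CnvPanel:
    """CNV segment change status for n samples x q2 segments (0/1)."""

    sample_ids: list[str]
    segment_ids: list[str]
    chromosomes: list[str]
    starts: np.ndarray  # int, 1-based inclusive
    ends: np.ndarray
    status: np.ndarray  # int8 (n, q2) in {0, 1}

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.status = np.asarray(self.status)
        if not np.isin(self.status, (0, 1)).all():
            bad = np.unique(self.status[~np.isin(self.status, (0, 1))])
            raise DataFormatError(f"CNV status values outside {{0,1}}: {bad.tolist()}")
        self.status = self.status.astype(np.int8)
        n, q2 = self.status.shape
        if n != len(self.sample_ids):
            raise DataFormatError(
                f"status rows ({n}) != sample count ({len(self.sample_ids)})"
            )
        if q2 != len(self.segment_ids) or q2 != self.starts.size or q2 != self.ends.size:
            raise DataFormatError("segment metadata length mismatch")
        if (self.starts > self.ends).any():
            raise DataFormatError("CNV segment with start > end")

    @property
    def n_samples(self) -> int:
        return self.status.shape[0]

    @property
    def n_segments(self) -> int:
        return self.status.shape[1]

    def subset_segments(self, idx: np.ndarray) -> "CnvPanel":
        idx = np.asarray(idx)
        return CnvPanel(
            sample_ids=self.sample_ids,
            segment_ids=[self.segment_ids[i] for i in idx],
            chromosomes=[self.chromosomes[i] for i in idx],
            starts=self.starts[idx],
            ends=self.ends[idx],
            status=self.status[:, idx],
        )

    def subset_samples(self, rows: np.ndarray) -> "CnvPanel":
        rows = np.asarray(rows)
        return CnvPanel(
            sample_ids=[self.sample_ids[i] for i in rows],
            segment_ids=self.segment_ids,
            chromosomes=self.chromosomes,
            starts=self.starts,
            ends=self.ends,
            status=self.status[rows, :],
        )


@dataclass
class CombinedGeneMatrix:
    """The joint SNV+CNV marker matrix for one gene or window.

    Columns are ordered all-SNVs-then-all-CNV-segments; ``marker_types``
    carries 1 for SNV columns and 2 for CNV columns.  Marker coordinates are
    retained so the matrix can be re-partitioned into moving windows.
    """

    unit_id: str
    chromosome: str
    start: int
    end: int
    sample_ids: list[str]
    snv_block: np.ndarray  # (n, q1)
    cnv_block: np.ndarray  # (n, q2)
    snv_ids: list[str] = field(default_factory=list)
    snv_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cnv_ids: list[str] = field(default_factory=list)
    cnv_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    cnv_ends: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def q1(self) -> int:
        return self.snv_block.shape[1]

    @property
    def q2(self) -> int:
        return self.cnv_block.shape[1]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def is_empty(self) -> bool:
        return self.q1 + self.q2 == 0

    @property
    def marker_types(self) -> np.ndarray:
        return np.concatenate([np.ones(self.q1, dtype=int), np.full(self.q2, 2)])

    @property
    def values(self) -> np.ndarray:
        """The n x (q1+q2) matrix, SNV columns first."""
        return np.concatenate(
            [self.snv_block, self.cnv_block.astype(float)], axis=1
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_geno_token(tok: str, path: str, lineno: int) -> float:
    if tok in MISSING_TOKENS:
        return np.nan
    try:
        v = float(tok)
    except ValueError as exc:
        raise DataFormatError(
            f"{path}:{lineno}: unparseable genotype {tok!r}"
        ) from exc
    if v not in (0.0, 1.0, 2.0):
        raise DataFormatError(f"{path}:{lineno}: genotype {tok!r} not in {{0,1,2,NA}}")
    return v


def _orient_minor(genotypes: np.ndarray) -> np.ndarray:
    """Flip markers so the counted allele is the minor (less frequent) one."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        af = np.nanmean(genotypes, axis=0) / 2.0
    flip = af > 0.5
    out = genotypes.copy()
    out[:, flip] = 2.0 - out[:, flip]
    return out


def read_snv_panel(path: str, format_name: str = "tsv-matrix") -> SnvPanel:
    """Read SNV genotypes from a PLINK .traw table, a VCF, or a TSV matrix.

    Both text-table formats are markers x samples with leading marker
    metadata columns.  The counted allele is re-oriented to the minor allele
    per marker from the observed sample allele frequency.
    """
    if format_name == "tsv-matrix":
        return _read_tsv_matrix(path)
    if format_name == "plink-traw":
        return _read_traw(path)
    if format_name == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown SNV format {format_name!r}")


def _read_tsv_matrix(path: str) -> SnvPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker_id", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise DataFormatError(
            f"{path}: expected leading columns {required}, got {list(df.columns[:3])}"
        )
    sample_ids = list(df.columns[3:])
    geno = np.empty((len(sample_ids), len(df)), dtype=float)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, sid in enumerate(sample_ids):
            geno[i, j] = _parse_geno_token(str(row[sid]).strip(), path, j + 2)
    return SnvPanel(
        sample_ids=sample_ids,
        marker_ids=df["marker_id"].tolist(),
        chromosomes=df["chrom"].astype(str).tolist(),
        positions=df["pos"].astype(np.int64).to_numpy(),
        genotypes=_orient_minor(geno),
    )


def _read_traw(path: str) -> SnvPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    if list(df.columns[: len(meta)]) != meta:
        raise DataFormatError(f"{path}: not a PLINK .traw header: {list(df.columns[:6])}")
    sample_ids = list(df.columns[len(meta):])
    geno = np.empty((len(sample_ids), len(df)), dtype=float)
    for j in range(len(df)):
        for i, sid in enumerate(sample_ids):
            geno[i, j] = _parse_geno_token(str(df.iloc[j][sid]).strip(), path, j + 2)
    return SnvPanel(
        sample_ids=sample_ids,
        marker_ids=df["SNP"].tolist(),
        chromosomes=df["CHR"].astype(str).tolist(),
        positions=df["POS"].astype(np.int64).to_numpy(),
        genotypes=_orient_minor(geno),
    )


def _read_vcf(path: str) -> SnvPanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    ids, chroms, poss, cols = [], [], [], []
    for k, var in enumerate(vcf):
        gts = np.asarray(var.genotypes, dtype=object)
        col = np.empty(len(sample_ids), dtype=float)
        for i, g in enumerate(var.genotypes):
            a = [x for x in g[:-1]]  # drop phasing flag
            if any(x is None or x < 0 for x in a):
                col[i] = np.nan
            else:
                col[i] = float(sum(1 for x in a if x > 0))
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))  # cyvcf2 POS is 1-based
        cols.append(col)
    geno = (
        np.stack(cols, axis=1) if cols else np.empty((len(sample_ids), 0))
    )
    return SnvPanel(
        sample_ids=sample_ids,
        marker_ids=ids,
        chromosomes=chroms,
        positions=np.asarray(poss, dtype=np.int64),
        genotypes=_orient_minor(geno),
    )


def write_snv_panel(panel: SnvPanel, path: str) -> None:
    """Write a panel in the tsv-matrix dialect ('.' for missing)."""
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tpos\t" + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_markers):
            vals = [
                "."
                if np.isnan(panel.genotypes[i, j])
                else f"{panel.genotypes[i, j]:g}"
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"{panel.marker_ids[j]}\t{panel.chromosomes[j]}\t{panel.positions[j]}\t"
                + "\t".join(vals)
                + "\n"
            )


def read_cnv_panel(
    segments_path: str,
    status_path: str,
    status_format: str = "auto",
) -> CnvPanel:
    """Read CNV segment definitions (BED) plus per-sample 0/1 status.

    ``segments_path`` is BED-like (chrom, start, end, segment_id; 0-based
    half-open, converted to 1-based closed).  ``status_path`` is either long
    format (sample, segment, status) or wide (sample_id + one column per
    segment).  Overlapping segments are kept as distinct columns; status
    values other than 0/1 are rejected.
    """
    seg = pd.read_csv(
        segments_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "segment_id"],
        dtype={"chrom": str, "segment_id": str},
        comment="#",
    )
    seg["start"] = seg["start"].astype(np.int64) + 1  # BED -> 1-based closed
    seg["end"] = seg["end"].astype(np.int64)

    st = pd.read_csv(status_path, sep="\t", dtype=str)
    if status_format == "auto":
        status_format = (
            "long"
            if list(st.columns[:3]) == ["sample", "segment", "status"]
            else "wide"
        )
    if status_format == "long":
        wide = st.pivot(index="sample", columns="segment", values="status")
    elif status_format == "wide":
        wide = st.set_index(st.columns[0])
    else:
        raise ValueError(f"unknown status format {status_format!r}")

    missing = [s for s in seg["segment_id"] if s not in wide.columns]
    if missing:
        raise DataFormatError(f"{status_path}: no status column for segments {missing}")
    wide = wide[list(seg["segment_id"])]
    try:
        status = wide.astype(float).to_numpy()
    except ValueError as exc:
        raise DataFormatError(f"{status_path}: non-numeric status value") from exc
    if np.isnan(status).any():
        raise DataFormatError(f"{status_path}: missing CNV status not allowed")
    if not np.isin(status, (0.0, 1.0)).all():
        bad = np.unique(status[~np.isin(status, (0.0, 1.0))])
        raise DataFormatError(f"{status_path}: status values outside {{0,1}}: {bad.tolist()}")
    return CnvPanel(
        sample_ids=[str(s) for s in wide.index],
        segment_ids=seg["segment_id"].tolist(),
        chromosomes=seg["chrom"].tolist(),
        starts=seg["start"].to_numpy(),
        ends=seg["end"].to_numpy(),
        status=status.astype(np.int8),
    )


def write_cnv_panel(panel: CnvPanel, segments_path: str, status_path: str) -> None:
    with open(segments_path, "w") as fh:
        for j in range(panel.n_segments):
            fh.write(
                f"{panel.chromosomes[j]}\t{panel.starts[j] - 1}\t{panel.ends[j]}\t"
                f"{panel.segment_ids[j]}\n"
            )
    wide = pd.DataFrame(
        panel.status, index=panel.sample_ids, columns=panel.segment_ids
    )
    wide.index.name = "sample_id"
    wide.to_csv(status_path, sep="\t")


def read_gene_annotations(path: str) -> list[GeneAnnotation]:
    """Read gene/region intervals from BED (0-based half-open on disk)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
        comment="#",
    )
    return [
        GeneAnnotation(
            gene_id=str(r["name"]),
            chromosome=str(r["chrom"]),
            start=int(r["start"]) + 1,
            end=int(r["end"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic marker.

    Conditional on the allele counts, the p-value sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed table (the standard exact HWE test).
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("HWE test undefined for empty genotype table")
    n_minor = 2 * n_hom_minor + n_het
    m = min(n_minor, 2 * n - n_minor)  # rarer allele count
    obs_het = n_het
    # P(het = h | n, m) over h with the parity of m, 0 <= h <= m,
    # and hom-minor = (m - h)/2 <= n etc.  Computed in log space.
    hs = np.arange(m % 2, m + 1, 2)
    hom_rare = (m - hs) // 2
    hom_common = n - hs - hom_rare
    valid = hom_common >= 0
    hs, hom_rare, hom_common = hs[valid], hom_rare[valid], hom_common[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_common + 1)
        - gammaln(hs + 1)
        - gammaln(hom_rare + 1)
        + hs * np.log(2.0)
        + gammaln(m + 1)
        + gammaln(2 * n - m + 1)
        - gammaln(2 * n + 1)
    )
    p_all = np.exp(logp - logp.max())
    p_all /= p_all.sum()
    p_obs = p_all[hs == obs_het]
    if p_obs.size == 0:  # observed table inconsistent with allele counts
        raise ValueError("observed heterozygote count has wrong parity")
    p = float(p_all[p_all <= p_obs[0] * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def qc_snv(
    panel: SnvPanel,
    max_missing_rate: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[SnvPanel, pd.DataFrame]:
    """Drop markers failing missingness or exact-HWE thresholds.

    Mirrors common array QC: remove markers with missing fraction strictly
    above ``max_missing_rate`` or HWE exact-test p strictly below
    ``hwe_alpha``.  Returns the filtered panel and a report of removals.
    """
    if not (0 < max_missing_rate < 1 and 0 < hwe_alpha < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    rows = []
    keep = []
    for j in range(panel.n_markers):
        g = panel.genotypes[:, j]
        miss = float(np.isnan(g).mean())
        if miss > max_missing_rate:
            rows.append((panel.marker_ids[j], "missing_rate", miss))
            continue
        obs = g[~np.isnan(g)]
        counts = [int((obs == k).sum()) for k in (0, 1, 2)]
        if sum(counts) > 0:
            p = hwe_exact_pvalue(*counts)
            if p < hwe_alpha:
                rows.append((panel.marker_ids[j], "hwe", p))
                continue
        keep.append(j)
    report = pd.DataFrame(rows, columns=["marker_id", "reason", "value"])
    return panel.subset_markers(np.asarray(keep, dtype=int)), report


def impute_missing(panel: SnvPanel, strategy: str = "mean") -> SnvPanel:
    """Replace missing genotypes by the marker mean (default) or zero.

    Markers missing in every sample carry no information and are dropped
    with a warning.
    """
    if strategy not in ("mean", "zero"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    g = panel.genotypes.copy()
    all_missing = np.isnan(g).all(axis=0)
    if all_missing.any():
        dropped = [panel.marker_ids[j] for j in np.where(all_missing)[0]]
        warnings.warn(f"dropping all-missing markers: {dropped}")
        panel = panel.subset_markers(np.where(~all_missing)[0])
        g = panel.genotypes.copy()
    nan_mask = np.isnan(g)
    if nan_mask.any():
        if strategy == "mean":
            col_mean = np.nanmean(g, axis=0)
            g[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
        else:
            g[nan_mask] = 0.0
    return replace(panel, genotypes=g)


# ---------------------------------------------------------------------------
# Mapping markers to genes and windows
# ---------------------------------------------------------------------------

def _snv_in_interval(snv: SnvPanel, region: GeneAnnotation) -> np.ndarray:
    chrom = np.asarray(snv.chromosomes) == region.chromosome
    return np.where(
        chrom & (snv.positions >= region.start) & (snv.positions <= region.end)
    )[0]


def _cnv_overlapping(
    cnv: CnvPanel, region: GeneAnnotation, min_overlap_frac: float
) -> np.ndarray:
    chrom = np.asarray(cnv.chromosomes) == region.chromosome
    ov_start = np.maximum(cnv.starts, region.start)
    ov_end = np.minimum(cnv.ends, region.end)
    overlap = np.maximum(ov_end - ov_start + 1, 0)
    ok = chrom & (overlap >= 1)
    if min_overlap_frac > 0:
        seg_len = cnv.ends - cnv.starts + 1
        ok &= overlap >= min_overlap_frac * seg_len
    return np.where(ok)[0]


def build_gene_matrix(
    snv: SnvPanel,
    cnv: CnvPanel,
    gene: GeneAnnotation,
    flank_bp: int = 0,
    min_overlap_frac: float = 0.0,
) -> CombinedGeneMatrix:
    """Assemble the combined SNV+CNV matrix for one genomic unit.

    An SNV belongs to the unit iff its position lies inside the (optionally
    flanked) closed interval; a CNV segment belongs iff it overlaps it by at
    least 1 bp (or ``min_overlap_frac`` of the segment length).  A unit with
    no markers is returned as an empty sentinel matrix.
    """
    if snv.sample_ids != cnv.sample_ids:
        raise DataFormatError("SNV and CNV panels must share sample order")
    region = GeneAnnotation(
        gene.gene_id,
        gene.chromosome,
        max(1, gene.start - flank_bp),
        gene.end + flank_bp,
    )
    si = _snv_in_interval(snv, region)
    ci = _cnv_overlapping(cnv, region, min_overlap_frac)
    return CombinedGeneMatrix(
        unit_id=gene.gene_id,
        chromosome=gene.chromosome,
        start=region.start,
        end=region.end,
        sample_ids=snv.sample_ids,
        snv_block=snv.genotypes[:, si],
        cnv_block=cnv.status[:, ci],
        snv_ids=[snv.marker_ids[i] for i in si],
        snv_positions=snv.positions[si],
        cnv_ids=[cnv.segment_ids[i] for i in ci],
        cnv_starts=cnv.starts[ci],
        cnv_ends=cnv.ends[ci],
    )


def build_window_matrices(
    gene_matrix: CombinedGeneMatrix,
    window_size_bp: int,
    step_bp: int | None = None,
) -> list[CombinedGeneMatrix]:
    """Partition a gene matrix into moving windows along the gene span.

    Windows start at the gene start and advance by ``step_bp`` (default:
    tiling, step = size); the last window may be short.  Membership follows
    the gene-level rules: SNV by position, CNV segment by >= 1 bp overlap,
    so a long segment appears in every window it spans.  Marker-free windows
    are emitted as empty sentinels to keep window coordinates addressable.
    """
    if window_size_bp <= 0:
        raise ValueError("window_size_bp must be positive")
    step = step_bp if step_bp is not None else window_size_bp
    if step <= 0:
        raise ValueError("step_bp must be positive")
    gm = gene_matrix
    out: list[CombinedGeneMatrix] = []
    k = 0
    start = gm.start
    while start <= gm.end:
        end = min(start + window_size_bp - 1, gm.end)
        si = np.where((gm.snv_positions >= start) & (gm.snv_positions <= end))[0]
        ci = np.where(
            (gm.cnv_starts <= end) & (gm.cnv_ends >= start)
        )[0]
        out.append(
            CombinedGeneMatrix(
                unit_id=f"{gm.unit_id}:w{k}",
                chromosome=gm.chromosome,
                start=start,
                end=end,
                sample_ids=gm.sample_ids,
                snv_block=gm.snv_block[:, si],
                cnv_block=gm.cnv_block[:, ci],
                snv_ids=[gm.snv_ids[i] for i in si],
                snv_positions=gm.snv_positions[si],
                cnv_ids=[gm.cnv_ids[i] for i in ci],
                cnv_starts=gm.cnv_starts[ci],
                cnv_ends=gm.cnv_ends[ci],
            )
        )
        k += 1
        start += step
    return out
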