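"""Two-stage co-localization pipeline: gene screen, then moving-window scan.

Stage 1 maps SNVs and CNV segments into each gene's combined matrix and
runs the region test to screen for candidate genes.  Stage 2 slides a
window across each screened gene and repeats the test per window on the
much smaller local matrix, co-localizing the concurrent SNV+CNV signal.
Window rows also carry SNV-only and CNV-only p-values so the three
"skylines" (-log10 p along the gene) can be compared.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_data import (
    CnvPanel,
    CombinedGeneMatrix,
    GeneAnnotation,
    SnvPanel,
    build_gene_matrix,
    build_window_matrices,
)
from .region_test import NullModel, TestConfig, RegionTestResult, fit_null, test_unit

__all__ = [
    "ScreenPolicy",
    "GeneScreenResult",
    "SkylineRow",
    "screen_genes",
    "colocalize",
    "run_inco",
]

log = logging.getLogger("inco")


@dataclass
class ScreenPolicy:
    """Significance policy for the two stages.

    ``gene_alpha`` applies to stage-1 adjusted p-values under ``correction``
    (none, bonferroni, or benjamini-hochberg across the screened genes);
    ``window_alpha`` applies per window in stage 2.  The default window is
    a 500 bp tile (step = size).
    """

    gene_alpha: float = 0.05
    correction: str = "none"
    window_alpha: float = 0.05
    window_size_bp: int = 500
    step_bp: int | None = None
    method: str = "skat-o"
    one_stage: bool = False

    def __post_init__(self) -> None:
        for a in (self.gene_alpha, self.window_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError(f"significance level {a} outside (0, 1)")
        if self.correction not in ("none", "bonferroni", "benjamini-hochberg"):
            raise ValueError(f"unknown correction {self.correction!r}")


@dataclass
class GeneScreenResult:
    gene: GeneAnnotation
    result: RegionTestResult
    p_adjusted: float
    selected: bool


@dataclass
class SkylineRow:
    """One moving-window record: joint, SNV-only and CNV-only p-values."""

    gene_id: str
    window_index: int
    start: int
    end: int
    q1: int
    q2: int
    p_combined: float | None
    p_snv: float | None
    p_cnv: float | None
    significant: bool

    @property
    def is_empty(self) -> bool:
        return self.q1 + self.q2 == 0


def _adjust(pvals: np.ndarray, correction: str) -> np.ndarray:
    if correction == "none":
        return pvals.copy()
    if correction == "bonferroni":
        return np.minimum(pvals * pvals.size, 1.0)
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def screen_genes(
    snv: SnvPanel,
    cnv: CnvPanel,
    genes: list[GeneAnnotation],
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    policy: ScreenPolicy | None = None,
    config: TestConfig | None = None,
    kind: str = "binary",
    null: NullModel | None = None,
) -> list[GeneScreenResult]:
    """Stage 1: test every non-empty gene's combined matrix; flag candidates.

    All genes are reported with their raw and adjusted p-values; a gene is
    selected iff its adjusted p falls below ``gene_alpha``.
    """
    policy = policy or ScreenPolicy()
    config = config or TestConfig()
    if null is None:
        null = fit_null(phenotype, covariates, kind)
    mats = [build_gene_matrix(snv, cnv, g) for g in genes]
    kept = [(g, m) for g, m in zip(genes, mats) if not m.is_empty]
    if not kept:
        raise ValueError("no gene contains any marker")
    results: list[RegionTestResult] = []
    for g, m in kept:
        try:
            results.append(test_unit(m, null, config, policy.method))
        except Exception as exc:
            raise RuntimeError(f"gene {g.gene_id}: region test failed") from exc
    p_adj = _adjust(np.array([r.p_value for r in results]), policy.correction)
    return [
        GeneScreenResult(g, r, float(pa), bool(pa < policy.gene_alpha))
        for (g, _), r, pa in zip(kept, results, p_adj)
    ]


def colocalize(
    gene: GeneAnnotation,
    snv: SnvPanel,
    cnv: CnvPanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    policy: ScreenPolicy | None = None,
    config: TestConfig | None = None,
    kind: str = "binary",
    null: NullModel | None = None,
    skylines: bool = True,
) -> list[SkylineRow]:
    """Stage 2: moving-window joint tests across one gene.

    Every marker-containing window gets the combined test; with
    ``skylines=True`` the SNV-only and CNV-only sub-matrices are tested with
    the same region test for comparability.  Empty windows yield sentinel
    rows so the skyline keeps its gaps.
    """
    policy = policy or ScreenPolicy()
    config = config or TestConfig()
    if null is None:
        null = fit_null(phenotype, covariates, kind)
    gm = build_gene_matrix(snv, cnv, gene)
    windows = build_window_matrices(gm, policy.window_size_bp, policy.step_bp)
    rows: list[SkylineRow] = []
    for k, w in enumerate(windows):
        if w.is_empty:
            rows.append(
                SkylineRow(gene.gene_id, k, w.start, w.end, 0, 0, None, None, None, False)
            )
            continue
        p_comb = test_unit(w, null, config, policy.method).p_value
        p_snv = p_cnv = None
        if skylines:
            if w.q1:
                snv_only = dataclasses.replace(
                    w, cnv_block=w.cnv_block[:, :0], cnv_ids=[],
                    cnv_starts=w.cnv_starts[:0], cnv_ends=w.cnv_ends[:0],
                )
                p_snv = test_unit(snv_only, null, config, policy.method).p_value
            if w.q2:
                cnv_only = dataclasses.replace(
                    w, snv_block=w.snv_block[:, :0], snv_ids=[],
                    snv_positions=w.snv_positions[:0],
                )
                p_cnv = test_unit(cnv_only, null, config, policy.method).p_value
        rows.append(
            SkylineRow(
                gene.gene_id, k, w.start, w.end, w.q1, w.q2,
                p_comb, p_snv, p_cnv, bool(p_comb < policy.window_alpha),
            )
        )
    return rows


def skyline_frame(rows: list[SkylineRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "window": r.window_index,
                "start": r.start,
                "end": r.end,
                "q1": r.q1,
                "q2": r.q2,
                "p_combined": r.p_combined if r.p_combined is not None else np.nan,
                "p_snv": r.p_snv if r.p_snv is not None else np.nan,
                "p_cnv": r.p_cnv if r.p_cnv is not None else np.nan,
                "significant": r.significant,
            }
            for r in rows
        ]
    )


def run_inco(
    snv: SnvPanel,
    cnv: CnvPanel,
    genes: list[GeneAnnotation],
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    policy: ScreenPolicy | None = None,
    config: TestConfig | None = None,
    kind: str = "binary",
    out_dir: str | Path | None = None,
    manifest_extra: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run the full two-stage analysis and optionally write result tables.

    Returns the gene table and one skyline table per scanned gene (all
    genes in one-stage mode, only screened candidates otherwise).  When
    ``out_dir`` is given, writes ``genes.tsv``, ``skyline_<gene>.tsv`` and a
    JSON run manifest; outputs are deterministic for a fixed input.
    """
    policy = policy or ScreenPolicy()
    config = config or TestConfig()
    null = fit_null(phenotype, covariates, kind)
    screened = screen_genes(
        snv, cnv, genes, phenotype, covariates, policy, config, kind, null
    )
    gene_table = pd.DataFrame(
        [
            {
                "gene_id": s.gene.gene_id,
                "chrom": s.gene.chromosome,
                "start": s.gene.start,
                "end": s.gene.end,
                "q1": s.result.q1,
                "q2": s.result.q2,
                "rho": s.result.rho,
                "p_value": s.result.p_value,
                "p_adjusted": s.p_adjusted,
                "selected": s.selected,
            }
            for s in screened
        ]
    )
    targets = [s.gene for s in screened if policy.one_stage or s.selected]
    log.info("screen: %d/%d genes selected", len(targets), len(screened))
    skymap: dict[str, pd.DataFrame] = {}
    for gene in targets:
        rows = colocalize(
            gene, snv, cnv, phenotype, covariates, policy, config, kind, null
        )
        skymap[gene.gene_id] = skyline_frame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gene_table.to_csv(out / "genes.tsv", sep="\t", index=False)
        for gid, df in skymap.items():
            df.to_csv(out / f"skyline_{gid}.tsv", sep="\t", index=False)
        manifest = {
            "command": "run",
            "n_samples": snv.n_samples,
            "n_genes": len(genes),
            "policy": dataclasses.asdict(policy),
            "weights": {
                "beta": list(config.beta_weight_params),
                "cnv": config.cnv_weight,
            },
            "rho_grid": list(config.rho_grid),
            "selected": [g.gene_id for g in targets],
        }
        manifest.update(manifest_extra or {})
        tmp = out / "manifest.json.tmp"
        tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        tmp.replace(out / "manifest.json")
    return gene_table, skymap
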