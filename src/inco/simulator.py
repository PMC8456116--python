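"""Synthetic genotype pool, case-control disease model, and the
operating-characteristic harness.

The pool emulates a biobank draw: a 21-gene panel with fixed per-gene SNV
and CNV-segment counts, a uniform minor-allele-frequency spectrum that
includes rare variants, low CNV carrier frequencies, and (optionally)
latent-Gaussian LD blocks among SNVs.  Disease status is generated from a
logistic model on one or two causal SNV+CNV pairs, including their product
(the concurrent effect); individuals are drawn from the pool with
replacement until the target numbers of cases and controls accrue.  The
harness runs the two-stage co-localization pipeline and the TUU/TIU
baselines replicate by replicate and tabulates false-positive, true-positive
and true-negative rates at gene and window level.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .comparators import single_marker_pvalues, stage1_select
from .genomic_data import (
    CnvPanel,
    CombinedGeneMatrix,
    GeneAnnotation,
    SnvPanel,
    build_gene_matrix,
    build_window_matrices,
)
from .pipeline import ScreenPolicy
from .region_test import TestConfig, fit_null, test_unit

__all__ = [
    "GeneSpec",
    "LdBlocks",
    "GenePoolSpec",
    "SimSetting",
    "SimPool",
    "MetricsTable",
    "table1_pool_spec",
    "load_settings",
    "generate_pool",
    "simulate_case_control",
    "evaluate_methods",
    "emit_report",
]

DEFAULT_GENE_LENGTH_BP = 10_000
DEFAULT_SEGMENT_LENGTH_RANGE = (500, 5_000)


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    chromosome: str
    q1: int
    q2: int
    length_bp: int = DEFAULT_GENE_LENGTH_BP


@dataclass(frozen=True)
class LdBlocks:
    """Exchangeable latent-Gaussian LD among SNVs.

    Haplotype alleles within a block share a latent factor with correlation
    ``latent_corr``; ``block_size`` of None puts each gene's SNVs in a
    single block.
    """

    latent_corr: float = 0.9
    block_size: int | None = None


@dataclass
class GenePoolSpec:
    """Blueprint of the synthetic marker pool."""

    genes: list[GeneSpec]
    pool_size: int = 20_000
    maf_range: tuple[float, float] = (0.01, 0.5)
    cnv_carrier_prob: float = 0.05
    causal_snv_maf: float = 0.05
    causal_cnv_prob: float = 0.05
    segment_length_range: tuple[int, int] = DEFAULT_SEGMENT_LENGTH_RANGE
    causal_window_bp: int = 500
    ld: LdBlocks | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("MAF range must lie in (0, 0.5]")
        for p in (self.cnv_carrier_prob, self.causal_snv_maf, self.causal_cnv_prob):
            if not 0.0 < p < 1.0:
                raise ValueError("probabilities must lie in (0, 1)")


@dataclass(frozen=True)
class SimSetting:
    """One row of the simulation design: log-odds effects of the disease model."""

    label: str
    beta: tuple[float, float, float]
    gamma: tuple[float, float, float] | None = None
    prevalence: float = 0.01
    verified: bool = True

    @property
    def is_null(self) -> bool:
        eff = self.beta + (self.gamma or ())
        return all(b == 0.0 for b in eff)


@dataclass(frozen=True)
class CausalRegion:
    gene_id: str
    snv_id: str
    cnv_id: str
    snv_col: int  # column index in the pool-wide SNV panel
    cnv_col: int


@dataclass
class SimPool:
    snv: SnvPanel
    cnv: CnvPanel
    genes: list[GeneAnnotation]
    causal: list[CausalRegion]
    spec: GenePoolSpec


def table1_pool_spec(**overrides) -> GenePoolSpec:
    """Pool spec with the bundled 21-gene panel (per-gene q1/q2 counts)."""
    ref = importlib.resources.files("inco").joinpath("data/table1.yaml")
    cfg = yaml.safe_load(ref.read_text())
    genes = [GeneSpec(**g) for g in cfg["genes"]]
    return GenePoolSpec(genes=genes, **overrides)


def load_settings() -> dict[str, SimSetting]:
    """All bundled simulation settings (parts A and B) keyed by label."""
    ref = importlib.resources.files("inco").joinpath("data/settings.yaml")
    cfg = yaml.safe_load(ref.read_text())
    prev = float(cfg["prevalence"])
    out: dict[str, SimSetting] = {}
    for label, row in cfg["part_a"].items():
        out[label] = SimSetting(label, tuple(row["beta"]), None, prev)
    for label, row in cfg["part_b"].items():
        if row.get("verified", True) is False or row["beta"] is None:
            out[label] = SimSetting(label, (0.0, 0.0, 0.0), None, prev, verified=False)
        else:
            out[label] = SimSetting(label, tuple(row["beta"]), tuple(row["gamma"]), prev)
    return out


# ---------------------------------------------------------------------------
# Pool generation
# ---------------------------------------------------------------------------

def _ld_genotypes(
    rng: np.random.Generator, n: int, maf: np.ndarray, ld: LdBlocks
) -> np.ndarray:
    """Genotypes with exchangeable within-block LD via a latent threshold model.

    Each haplotype's latent vector is sqrt(r) * shared + sqrt(1-r) * own;
    an allele is minor when its latent value falls below the MAF quantile,
    so marginal frequencies are preserved while nearby markers correlate.
    """
    q = maf.size
    r = ld.latent_corr
    bs = ld.block_size or q
    thr = norm.ppf(maf)
    geno = np.zeros((n, q), dtype=np.int8)
    for b0 in range(0, q, bs):
        b1 = min(b0 + bs, q)
        width = b1 - b0
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            z = np.sqrt(r) * shared + np.sqrt(1.0 - r) * rng.standard_normal((n, width))
            geno[:, b0:b1] += (z < thr[None, b0:b1]).astype(np.int8)
    return geno


def generate_pool(spec: GenePoolSpec, seed: int) -> SimPool:
    """Draw the marker pool: coordinates, allele frequencies, genotypes.

    Genes are laid out on their nominal chromosomes at well-separated
    offsets.  SNV positions are uniform within the gene span; CNV segments
    get uniform lengths and are placed to lie within the gene.  The first
    gene hosts two designated causal SNV+CNV pairs: one in the first
    window tile of the gene, one in the last (used as region 2 in
    two-region settings).
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"pool{i}" for i in range(spec.pool_size)]
    genes: list[GeneAnnotation] = []
    snv_ids, snv_chrom, snv_pos, snv_maf = [], [], [], []
    cnv_ids, cnv_chrom, cnv_start, cnv_end, cnv_prob = [], [], [], [], []
    causal: list[CausalRegion] = []
    wbp = spec.causal_window_bp

    for gi, g in enumerate(spec.genes):
        start = 1_000_000 * (gi + 1)
        end = start + g.length_bp - 1
        genes.append(GeneAnnotation(g.gene_id, g.chromosome, start, end))

        pos = np.sort(rng.integers(start, end + 1, g.q1))
        maf = rng.uniform(*spec.maf_range, g.q1)
        seg_len = rng.integers(*spec.segment_length_range, g.q2, endpoint=True)
        seg_start = np.array(
            [rng.integers(start, max(start + 1, end - sl + 2)) for sl in seg_len]
        )
        seg_end = np.minimum(seg_start + seg_len - 1, end)
        prob = np.full(g.q2, spec.cnv_carrier_prob)

        if gi == 0:
            # plant the causal pairs: first tile and last tile of the gene
            if g.q1 < 2 or g.q2 < 2:
                raise ValueError("first gene needs >= 2 SNVs and >= 2 segments")
            # causal SNV and CNV segment co-localized inside one window
            # tile: region 1 in the first tile, region 2 in the last
            pos[0] = rng.integers(start, start + wbp)
            pos[-1] = rng.integers(end - wbp + 1, end + 1)
            maf[0] = spec.causal_snv_maf
            maf[-1] = spec.causal_snv_maf
            len1 = rng.integers(wbp // 2, wbp + 1)
            seg_start[0] = rng.integers(start, start + wbp - len1 + 1)
            seg_end[0] = seg_start[0] + len1 - 1
            len2 = rng.integers(wbp // 2, wbp + 1)
            seg_start[-1] = rng.integers(end - wbp + 1, end - len2 + 2)
            seg_end[-1] = seg_start[-1] + len2 - 1
            prob[0] = spec.causal_cnv_prob
            prob[-1] = spec.causal_cnv_prob
            order = np.argsort(pos)
            pos, maf = pos[order], maf[order]
            causal_snv_local = (int(np.where(order == 0)[0][0]), int(np.where(order == g.q1 - 1)[0][0]))

        snv_ids += [f"{g.gene_id}_snv{j}" for j in range(g.q1)]
        snv_chrom += [g.chromosome] * g.q1
        snv_pos.append(pos)
        snv_maf.append(maf)
        cnv_ids += [f"{g.gene_id}_seg{j}" for j in range(g.q2)]
        cnv_chrom += [g.chromosome] * g.q2
        cnv_start.append(seg_start)
        cnv_end.append(seg_end)
        cnv_prob.append(prob)

    snv_pos = np.concatenate(snv_pos)
    snv_maf = np.concatenate(snv_maf)
    cnv_start = np.concatenate(cnv_start)
    cnv_end = np.concatenate(cnv_end)
    cnv_prob = np.concatenate(cnv_prob)

    if spec.ld is None:
        geno = rng.binomial(2, snv_maf, (spec.pool_size, snv_maf.size)).astype(np.int8)
    else:
        parts = []
        off = 0
        for g in spec.genes:
            parts.append(
                _ld_genotypes(rng, spec.pool_size, snv_maf[off : off + g.q1], spec.ld)
            )
            off += g.q1
        geno = np.concatenate(parts, axis=1)
    status = (
        rng.random((spec.pool_size, cnv_prob.size)) < cnv_prob[None, :]
    ).astype(np.int8)

    snv = SnvPanel(sample_ids, snv_ids, snv_chrom, snv_pos, geno.astype(float))
    cnv = CnvPanel(sample_ids, cnv_ids, cnv_chrom, cnv_start, cnv_end, status)

    g0 = spec.genes[0]
    i_first, i_last = causal_snv_local
    causal = [
        CausalRegion(g0.gene_id, snv_ids[i_first], cnv_ids[0], i_first, 0),
        CausalRegion(
            g0.gene_id, snv_ids[i_last], cnv_ids[g0.q2 - 1], i_last, g0.q2 - 1
        ),
    ]
    return SimPool(snv, cnv, genes, causal, spec)


# ---------------------------------------------------------------------------
# Disease model and case-control sampling
# ---------------------------------------------------------------------------

def _linear_predictor(
    pool: SimPool, setting: SimSetting, beta0_literal: bool = False
) -> np.ndarray:
    """Per-pool-individual log-odds of disease under the setting.

    The generative SNV coding is dominant (carrier of >= 1 minor allele);
    analysis keeps the additive 0/1/2 coding, mirroring the deliberate
    mismatch between data generation and analysis model.
    """
    b0 = setting.prevalence if beta0_literal else float(logit(setting.prevalence))
    r1 = pool.causal[0]
    d1 = (pool.snv.genotypes[:, r1.snv_col] > 0).astype(float)
    c1 = pool.cnv.status[:, r1.cnv_col].astype(float)
    b1, b2, b3 = setting.beta
    lp = b0 + b1 * d1 + b2 * c1 + b3 * d1 * c1
    if setting.gamma is not None:
        r2 = pool.causal[1]
        d2 = (pool.snv.genotypes[:, r2.snv_col] > 0).astype(float)
        c2 = pool.cnv.status[:, r2.cnv_col].astype(float)
        g1, g2, g3 = setting.gamma
        lp = lp + g1 * d2 + g2 * c2 + g3 * d2 * c2
    return lp


class AccrualError(RuntimeError):
    """Case/control accrual exceeded the draw budget."""


def simulate_case_control(
    setting: SimSetting,
    pool: SimPool,
    seed: int | np.random.Generator,
    n_per_group: int = 200,
    beta0_literal: bool = False,
    max_draws: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n cases and n controls from the pool under the disease model.

    Individuals are drawn with replacement; disease status is Bernoulli on
    the logistic scale; accrual continues until both groups are filled.
    Returns (phenotype 0/1 vector, pool row indices), cases first.
    """
    if not setting.verified:
        raise ValueError(
            f"setting {setting.label} ships as an unverified placeholder"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p = expit(_linear_predictor(pool, setting, beta0_literal))
    budget = max_draws or max(2_000_000, int(80 * n_per_group / setting.prevalence))
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    n_cases = n_controls = 0
    drawn = 0
    chunk = max(4096, int(2.5 * n_per_group / setting.prevalence))
    while n_cases < n_per_group or n_controls < n_per_group:
        if drawn >= budget:
            raise AccrualError(
                f"{setting.label}: drew {drawn} individuals but accrued only "
                f"{n_cases} cases / {n_controls} controls of {n_per_group}; "
                "prevalence may be too low for the draw budget"
            )
        size = min(chunk, budget - drawn)
        idx = rng.integers(0, pool.spec.pool_size, size)
        y = rng.random(size) < p[idx]
        drawn += size
        if n_cases < n_per_group:
            cases.append(idx[y])
            n_cases += int(y.sum())
        if n_controls < n_per_group:
            controls.append(idx[~y])
            n_controls += int((~y).sum())
    rows = np.concatenate(
        [np.concatenate(cases)[:n_per_group], np.concatenate(controls)[:n_per_group]]
    )
    phenotype = np.concatenate(
        [np.ones(n_per_group), np.zeros(n_per_group)]
    )
    return phenotype, rows


# ---------------------------------------------------------------------------
# End-to-end evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsTable:
    """Operating characteristics per method for one setting and sample size.

    Rates use the conventions of the evaluation design: gene-level rates
    count gene-replicate selections; window-level rates count
    marker-containing windows across all genes, with windows of unscreened
    genes counted as not flagged.  ``fpr_region_evaluated`` additionally
    reports the rate among windows actually tested (screened genes only).
    Standard errors are binomial over replicates: sqrt(r (1 - r) / R).
    """

    frame: pd.DataFrame
    setting: str
    n_per_group: int
    replications: int
    subset_violations: int | None = field(default=None)

    def row(self, method: str) -> pd.Series:
        return self.frame.set_index("method").loc[method]


class _Tally:
    def __init__(self) -> None:
        self.counts: dict[str, list[int]] = {}

    def add(self, key: str, hits: int, total: int) -> None:
        c = self.counts.setdefault(key, [0, 0])
        c[0] += hits
        c[1] += total

    def rate(self, key: str) -> float:
        hits, total = self.counts.get(key, [0, 0])
        return hits / total if total else float("nan")


def _window_layout(pool: SimPool, window_size_bp: int, step_bp: int | None):
    """Precompute, per gene, window membership and causal flags.

    Marker coordinates are fixed for a pool, so the window -> column-index
    mapping is computed once and reused across replicates.
    """
    causal_snv = {r.snv_id for r in pool.causal}
    causal_cnv = {r.cnv_id for r in pool.causal}
    layout = []
    for gene in pool.genes:
        gm = build_gene_matrix(pool.snv, pool.cnv, gene)
        windows = build_window_matrices(gm, window_size_bp, step_bp)
        snv_col = {m: i for i, m in enumerate(pool.snv.marker_ids)}
        cnv_col = {m: i for i, m in enumerate(pool.cnv.segment_ids)}
        wins = []
        for w in windows:
            if w.is_empty:
                continue
            wins.append(
                {
                    "template": w,
                    "snv_cols": np.array([snv_col[m] for m in w.snv_ids], dtype=int),
                    "cnv_cols": np.array([cnv_col[m] for m in w.cnv_ids], dtype=int),
                    "snv_ids": w.snv_ids,
                    "cnv_ids": w.cnv_ids,
                    "causal": bool(
                        causal_snv.intersection(w.snv_ids)
                        or causal_cnv.intersection(w.cnv_ids)
                    ),
                }
            )
        gene_cols_snv = np.array(
            [snv_col[m] for m in gm.snv_ids], dtype=int
        )
        gene_cols_cnv = np.array([cnv_col[m] for m in gm.cnv_ids], dtype=int)
        layout.append(
            {
                "gene": gene,
                "matrix_template": gm,
                "snv_cols": gene_cols_snv,
                "cnv_cols": gene_cols_cnv,
                "causal": gene.gene_id == pool.causal[0].gene_id,
                "windows": wins,
            }
        )
    return layout


def _fill(template: CombinedGeneMatrix, snv_rows, cnv_rows, sample_ids):
    import dataclasses

    return dataclasses.replace(
        template, sample_ids=sample_ids, snv_block=snv_rows, cnv_block=cnv_rows
    )


def evaluate_methods(
    setting: SimSetting,
    pool_spec: GenePoolSpec | None = None,
    pool: SimPool | None = None,
    n_per_group: int = 200,
    replications: int = 1_000,
    seed: int = 0,
    methods: tuple[str, ...] = ("inco", "tuu", "tiu"),
    policy: ScreenPolicy | None = None,
    config: TestConfig | None = None,
    marker_alpha: float = 0.05,
    beta0_literal: bool = False,
) -> MetricsTable:
    """Replicate-level evaluation of INCO against the TUU/TIU baselines.

    Per replicate: draw a case-control sample from the pool, fit one null
    model, run the two-stage pipeline and the per-marker baselines on the
    same data, and tally gene- and window-level selections against the
    causal layout.
    """
    policy = policy or ScreenPolicy()
    config = config or TestConfig()
    ss = np.random.SeedSequence(seed)
    pool_seed, sample_seed = ss.spawn(2)
    if pool is None:
        if pool_spec is None:
            pool_spec = table1_pool_spec()
        pool = generate_pool(pool_spec, pool_seed.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(sample_seed.generate_state(2))
    layout = _window_layout(pool, policy.window_size_bp, policy.step_bp)
    active_causal = 1 if setting.gamma is None else 2
    causal_snv = {r.snv_id for r in pool.causal[:active_causal]}
    causal_cnv = {r.cnv_id for r in pool.causal[:active_causal]}
    for g in layout:
        for w in g["windows"]:
            w["causal"] = bool(
                causal_snv.intersection(w["snv_ids"])
                or causal_cnv.intersection(w["cnv_ids"])
            )
    geno = pool.snv.genotypes
    status = pool.cnv.status

    tallies = {m: _Tally() for m in methods}
    subset_violations = 0  # gene-replicates selected by TIU but not TUU
    for _rep in range(replications):
        y, rows = simulate_case_control(
            setting, pool, rng, n_per_group, beta0_literal
        )
        null = fit_null(y, None, "binary")
        g_rows = geno[rows]
        c_rows = status[rows]
        sample_ids = [f"s{i}" for i in range(y.size)]

        if "tuu" in methods or "tiu" in methods:
            snv_p = single_marker_pvalues(g_rows, null)
            cnv_p = single_marker_pvalues(c_rows.astype(float), null)

        for gl in layout:
            is_causal_gene = gl["causal"] and not setting.is_null
            gsnv = g_rows[:, gl["snv_cols"]]
            gcnv = c_rows[:, gl["cnv_cols"]]

            if "inco" in methods:
                gm = _fill(gl["matrix_template"], gsnv, gcnv, sample_ids)
                res = test_unit(gm, null, config, policy.method)
                sel = res.p_value < policy.gene_alpha
                t = tallies["inco"]
                gk = "gene_causal" if is_causal_gene else "gene_noncausal"
                t.add(gk, int(sel), 1)
                any_hit = 0
                for w in gl["windows"]:
                    wkey = "win_causal" if (w["causal"] and not setting.is_null) else "win_noncausal"
                    if sel:
                        wm = _fill(
                            w["template"],
                            g_rows[:, w["snv_cols"]],
                            c_rows[:, w["cnv_cols"]],
                            sample_ids,
                        )
                        with warnings.catch_warnings():
                            # windows whose only markers drew no carriers are
                            # constant in this replicate; p = 1 by contract
                            warnings.simplefilter("ignore", UserWarning)
                            wp = test_unit(wm, null, config, policy.method).p_value
                        hit = int(wp < policy.window_alpha)
                        any_hit |= hit
                        t.add(wkey, hit, 1)
                        t.add(wkey + "_evaluated", hit, 1)
                    else:
                        t.add(wkey, 0, 1)
                t.add(gk + "_anywin", any_hit, 1)

            sel_by_mode: dict[str, bool] = {}
            for meth, mode in (("tuu", "union"), ("tiu", "intersection")):
                if meth not in methods:
                    continue
                t = tallies[meth]
                gp_snv = snv_p[gl["snv_cols"]]
                gp_cnv = cnv_p[gl["cnv_cols"]]
                sel = stage1_select(gp_snv, gp_cnv, mode, marker_alpha)
                sel_by_mode[meth] = sel
                gk = "gene_causal" if is_causal_gene else "gene_noncausal"
                t.add(gk, int(sel), 1)
                any_hit = 0
                for w in gl["windows"]:
                    wkey = "win_causal" if (w["causal"] and not setting.is_null) else "win_noncausal"
                    if sel:
                        hit = int(
                            (snv_p[w["snv_cols"]] < marker_alpha).any()
                            or (cnv_p[w["cnv_cols"]] < marker_alpha).any()
                        )
                        any_hit |= hit
                        t.add(wkey, hit, 1)
                        t.add(wkey + "_evaluated", hit, 1)
                    else:
                        t.add(wkey, 0, 1)
                t.add(gk + "_anywin", any_hit, 1)
            if "tuu" in sel_by_mode and "tiu" in sel_by_mode:
                subset_violations += int(sel_by_mode["tiu"] and not sel_by_mode["tuu"])

    rows_out = []
    R = replications
    for m in methods:
        t = tallies[m]
        fpr_g = t.rate("gene_noncausal")
        fpr_r = t.rate("win_noncausal")
        rec = {
            "method": m,
            "fpr_gene": fpr_g,
            "fpr_region": fpr_r,
            "fpr_region_evaluated": t.rate("win_noncausal_evaluated"),
            "fpr_region_anywin": t.rate("gene_noncausal_anywin"),
            "tpr_gene": t.rate("gene_causal"),
            "tpr_region": t.rate("win_causal"),
            "tpr_region_anywin": t.rate("gene_causal_anywin"),
            "tnr_gene": 1.0 - fpr_g if np.isfinite(fpr_g) else float("nan"),
            "tnr_region": 1.0 - fpr_r if np.isfinite(fpr_r) else float("nan"),
        }
        for k in ("fpr_gene", "fpr_region", "fpr_region_anywin", "tpr_gene", "tpr_region"):
            r = rec[k]
            rec[k + "_se"] = (
                float(np.sqrt(r * (1.0 - r) / R)) if np.isfinite(r) else float("nan")
            )
        rows_out.append(rec)
    table = MetricsTable(pd.DataFrame(rows_out), setting.label, n_per_group, R)
    table.subset_violations = (
        subset_violations if {"tuu", "tiu"} <= set(methods) else None
    )
    return table


def emit_report(table: MetricsTable, out_dir: str | Path, meta: dict | None = None) -> None:
    """Write the metrics as TSV plus a JSON provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(out / f"metrics_{table.setting}_n{table.n_per_group}.tsv",
                       sep="\t", index=False)
    side = {
        "setting": table.setting,
        "n_per_group": table.n_per_group,
        "replications": table.replications,
    }
    side.update(meta or {})
    (out / f"metrics_{table.setting}_n{table.n_per_group}.json").write_text(
        json.dumps(side, indent=2, sort_keys=True)
    )
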