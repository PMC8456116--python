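"""Traditional parallel integrative baselines: union-union and
intersection-union.

Each platform is analyzed separately with single-marker score tests.  In
stage 1 a gene is selected by the *union* rule if any of its SNVs or CNV
segments is significant, and by the *intersection* rule if at least one SNV
AND at least one CNV segment are.  In stage 2 both variants use the same
union rule over windows: a window is significant iff it contains at least
one marker (either platform) whose stage-1 p-value is below alpha.  Hence
the two baselines: TUU (union-union) and TIU (intersection-union).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_data import (
    CnvPanel,
    CombinedGeneMatrix,
    GeneAnnotation,
    SnvPanel,
    build_gene_matrix,
    build_window_matrices,
)
from .region_test import NullModel, fit_null

__all__ = [
    "MarkerTestResult",
    "single_marker_test",
    "single_marker_pvalues",
    "stage1_select",
    "stage2_windows",
    "run_traditional",
]


@dataclass
class MarkerTestResult:
    marker_id: str
    platform: str  # "SNV" | "CNV"
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def single_marker_pvalues(G: np.ndarray, null: NullModel) -> np.ndarray:
    """GLM score-test p-value per column of G (vectorized).

    For column g the score statistic (g'r)^2 / (g'P0 g) is chi-square with
    one degree of freedom under the null; constant columns give p = 1.
    """
    G = np.asarray(G, dtype=float)
    num = null.score(G) ** 2
    den = null.gram_diag(G)
    p = np.ones(G.shape[1])
    ok = den > 1e-12 * max(float(den.max(initial=0.0)), 1.0)
    p[ok] = stats.chi2.sf(num[ok] / den[ok], df=1)
    return p


def single_marker_test(
    marker_column: np.ndarray,
    null: NullModel,
    marker_id: str = "marker",
    platform: str = "SNV",
) -> MarkerTestResult:
    """Score test of a single marker column under the fitted null."""
    p = single_marker_pvalues(np.asarray(marker_column, dtype=float).reshape(-1, 1), null)
    return MarkerTestResult(marker_id, platform, float(p[0]))


def stage1_select(
    snv_pvalues: np.ndarray, cnv_pvalues: np.ndarray, mode: str, alpha: float
) -> bool:
    """Gene selection by set rule over per-marker p-values.

    union: any marker on either platform significant; intersection: at least
    one significant SNV AND one significant CNV segment (a gene lacking one
    platform can never pass intersection).
    """
    snv_hit = bool(snv_pvalues.size) and bool((snv_pvalues < alpha).any())
    cnv_hit = bool(cnv_pvalues.size) and bool((cnv_pvalues < alpha).any())
    if mode == "union":
        return snv_hit or cnv_hit
    if mode == "intersection":
        return snv_hit and cnv_hit
    raise ValueError(f"unknown stage-1 mode {mode!r}")


def stage2_windows(
    windows: list[CombinedGeneMatrix],
    snv_pvalues: dict[str, float],
    cnv_pvalues: dict[str, float],
    alpha: float,
) -> list[bool]:
    """Union rule per window: significant iff any contained marker is.

    Marker p-values are the stage-1 values, reused without re-fitting.
    """
    flags = []
    for w in windows:
        ps = [snv_pvalues[m] for m in w.snv_ids] + [cnv_pvalues[m] for m in w.cnv_ids]
        flags.append(any(p < alpha for p in ps))
    return flags


def run_traditional(
    snv: SnvPanel,
    cnv: CnvPanel,
    genes: list[GeneAnnotation],
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    mode: str = "tuu",
    alpha: float = 0.05,
    window_size_bp: int = 500,
    step_bp: int | None = None,
    kind: str = "binary",
    null: NullModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the TUU or TIU parallel analysis end to end.

    Output schema mirrors the two-stage pipeline (gene table + window
    table) so operating characteristics can be compared head to head.
    """
    if mode not in ("tuu", "tiu"):
        raise ValueError(f"mode must be 'tuu' or 'tiu', got {mode!r}")
    stage1_mode = "union" if mode == "tuu" else "intersection"
    if null is None:
        null = fit_null(phenotype, covariates, kind)
    snv_p = single_marker_pvalues(np.nan_to_num(snv.genotypes), null)
    cnv_p = single_marker_pvalues(cnv.status.astype(float), null)
    snv_map = dict(zip(snv.marker_ids, snv_p))
    cnv_map = dict(zip(cnv.segment_ids, cnv_p))

    gene_rows, window_rows = [], []
    for gene in genes:
        gm = build_gene_matrix(snv, cnv, gene)
        if gm.is_empty:
            continue
        g_snv_p = np.array([snv_map[m] for m in gm.snv_ids])
        g_cnv_p = np.array([cnv_map[m] for m in gm.cnv_ids])
        selected = stage1_select(g_snv_p, g_cnv_p, stage1_mode, alpha)
        gene_rows.append(
            {
                "gene_id": gene.gene_id,
                "q1": gm.q1,
                "q2": gm.q2,
                "min_p_snv": float(g_snv_p.min()) if g_snv_p.size else np.nan,
                "min_p_cnv": float(g_cnv_p.min()) if g_cnv_p.size else np.nan,
                "selected": selected,
            }
        )
        if selected:
            windows = build_window_matrices(gm, window_size_bp, step_bp)
            flags = stage2_windows(windows, snv_map, cnv_map, alpha)
            for k, (w, f) in enumerate(zip(windows, flags)):
                window_rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "window": k,
                        "start": w.start,
                        "end": w.end,
                        "q1": w.q1,
                        "q2": w.q2,
                        "significant": f and not w.is_empty,
                    }
                )
    return pd.DataFrame(gene_rows), pd.DataFrame(window_rows)
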