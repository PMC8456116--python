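"""Region-level association tests on the combined SNV+CNV matrix.

Implements the optimal weighted-kernel score test family (SKAT-O) under a
GLM null.  For a region matrix G (n x p), null-model residuals r = y - mu,
and column weights w, the family of statistics is

    Q_rho = S' R_rho S,   S = W G' r,   R_rho = (1 - rho) I + rho 11',

so rho = 0 is the variance-component (SKAT) statistic sum_j (w_j g_j'r)^2
and rho = 1 the squared weighted burden score.  Under the null each Q_rho
is a positive mixture of 1-df chi-squares with weights given by the
eigenvalues of R_rho^{1/2} A R_rho^{1/2}, A = W G' P0 G W, where
P0 = V - VX(X'VX)^{-1}X'V is the covariance of the null residuals.  Mixture
tail probabilities are computed by numerical inversion of the
characteristic function (Imhof's formula) with a four-moment (Liu-type)
approximation as fallback; the optimal test minimizes p over a rho grid and
corrects for the minimization by one-dimensional integration of the joint
null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .genomic_data import CombinedGeneMatrix

__all__ = [
    "NullModel",
    "TestConfig",
    "RegionTestResult",
    "fit_null",
    "beta_maf_weights",
    "region_weights",
    "q_statistic",
    "pvalue_quadform",
    "skat_o",
    "test_unit",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


class NullFitError(RuntimeError):
    """Null GLM failed to converge or the design is deficient."""


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Phenotype-on-covariates GLM fit shared by all region tests.

    Holds everything the score statistics need: fitted means, raw residuals,
    the working-variance weights v_i (mu(1-mu) for a binary trait, the
    residual variance for a continuous one), and the covariate design X.
    """

    kind: str  # "binary" | "continuous"
    y: np.ndarray
    mu: np.ndarray
    X: np.ndarray  # (n, c) including intercept
    v: np.ndarray  # per-sample variance weights
    dispersion: float
    converged: bool

    def __post_init__(self) -> None:
        self.resid = self.y - self.mu
        VX = self.X * self.v[:, None]
        self._VX = VX
        self._XtVX_inv = np.linalg.inv(self.X.T @ VX)

    @property
    def n_samples(self) -> int:
        return self.y.size

    def score(self, G: np.ndarray) -> np.ndarray:
        """G' (y - mu) for each column of G."""
        return G.T @ self.resid

    def gram(self, G: np.ndarray) -> np.ndarray:
        """G' P0 G with P0 = V - VX (X'VX)^-1 X'V (covariance of residuals)."""
        GtVG = (G * self.v[:, None]).T @ G
        GtVX = G.T @ self._VX
        return GtVG - GtVX @ self._XtVX_inv @ GtVX.T

    def gram_diag(self, G: np.ndarray) -> np.ndarray:
        """Diagonal of G' P0 G, vectorized across columns."""
        d1 = np.einsum("ij,ij->j", G * self.v[:, None], G)
        B = G.T @ self._VX
        d2 = np.einsum("ij,jk,ik->i", B, self._XtVX_inv, B)
        return d1 - d2


def fit_null(
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    kind: str = "binary",
) -> NullModel:
    """Fit the null GLM g(E[Y]) = Z alpha (intercept + covariates, no markers).

    Binary traits use a logistic fit by iteratively reweighted least squares
    (via statsmodels); continuous traits an ordinary least-squares fit.
    """
    import statsmodels.api as sm

    y = np.asarray(phenotype, dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing phenotype values are not allowed")
    n = y.size
    if covariates is None:
        X = np.ones((n, 1))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != n:
            Z = Z.T
        X = np.column_stack([np.ones(n), Z])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy inclusion
        bad = []
        kept = np.empty((n, 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
            else:
                bad.append(j)
        raise NullFitError(f"rank-deficient covariate design; redundant columns {bad}")

    if kind == "binary":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binary phenotype must be coded 0/1")
        if y.min() == y.max():
            raise NullFitError("phenotype is constant; logistic null undefined")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            except Exception as exc:  # pragma: no cover - statsmodels internals
                raise NullFitError(f"logistic null fit failed: {exc}") from exc
        mu = np.asarray(res.fittedvalues)
        if not res.converged or mu.min() < 1e-10 or mu.max() > 1 - 1e-10:
            raise NullFitError("logistic null did not converge (possible separation)")
        v = mu * (1.0 - mu)
        return NullModel("binary", y, mu, X, v, 1.0, True)
    if kind == "continuous":
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = X @ beta
        dof = n - X.shape[1]
        if dof <= 0:
            raise NullFitError("no residual degrees of freedom")
        sigma2 = float(((y - mu) ** 2).sum() / dof)
        if sigma2 <= 0:
            raise NullFitError("zero residual variance")
        v = np.full(n, sigma2)
        return NullModel("continuous", y, mu, X, v, sigma2, True)
    raise ValueError(f"unknown phenotype kind {kind!r}")


# ---------------------------------------------------------------------------
# Weights and configuration
# ---------------------------------------------------------------------------

@dataclass
class TestConfig:
    """Weight rule and rho grid for the optimal region test.

    SNV columns receive the Beta(a, b)-density-of-MAF weight (default
    Beta(1, 25), upweighting rare variants); CNV status columns have no
    allele frequency, so they receive the flat ``cnv_weight``.
    """

    __test__ = False  # not a pytest class despite the name

    beta_weight_params: tuple[float, float] = (1.0, 25.0)
    cnv_weight: float = 1.0
    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    pvalue_tol: float = 1e-6

    def __post_init__(self) -> None:
        g = tuple(sorted(self.rho_grid))
        if not g or g[0] < 0 or g[-1] > 1:
            raise ValueError("rho grid must lie within [0, 1]")
        self.rho_grid = g


def beta_maf_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta-density weights evaluated at the minor allele frequency."""
    return stats.beta.pdf(np.clip(np.asarray(maf, dtype=float), 0.0, 1.0), a, b)


def region_weights(matrix: CombinedGeneMatrix, config: TestConfig) -> np.ndarray:
    """Per-column weights: Beta(MAF) for SNVs, a flat weight for CNVs."""
    a, b = config.beta_weight_params
    if matrix.q1:
        maf = np.nanmean(matrix.snv_block, axis=0) / 2.0
        w_snv = beta_maf_weights(maf, a, b)
    else:
        w_snv = np.empty(0)
    return np.concatenate([w_snv, np.full(matrix.q2, config.cnv_weight)])


# ---------------------------------------------------------------------------
# Quadratic-form (chi-square mixture) tail probabilities
# ---------------------------------------------------------------------------

def _chernoff_cutoff(lam: np.ndarray, acc: float) -> float:
    """Smallest x with a Chernoff bound P(sum lam chi2_1 > x) <= acc."""
    lmax = lam.max()
    ts = np.linspace(0.05, 0.98, 20) / (2.0 * lmax)
    # exp(-t x - 0.5 sum log(1 - 2 t lam)) <= acc  =>  x >= (c_t + log(1/acc))/t
    c = -0.5 * np.log1p(-2.0 * ts[:, None] * lam[None, :]).sum(axis=1)
    xs = (c + np.log(1.0 / acc)) / ts
    return float(xs.min())


# Gaussian smoothing scale (in units of the mixture SD) used by the CF
# inversion; three geometrically spaced values feed a Richardson
# extrapolation in tau^2 that removes the smoothing bias to O(tau^6).
_SMOOTH_TAU = 0.045


def _imhof_tail_many(
    lambdas: np.ndarray, qs: np.ndarray, acc: float = 1e-9
) -> tuple[np.ndarray, float]:
    """P(sum_k lambda_k chi^2_1 > q_i) for several q by CF inversion.

    Gil-Pelaez inversion of the smoothed characteristic function on a
    uniform midpoint grid: the Gaussian factor makes the integrand decay
    exponentially, the grid spacing is set from a Chernoff tail bound so the
    midpoint rule's aliasing images carry mass below ``acc``, and the
    smoothing bias is removed by Richardson extrapolation over three
    smoothing scales.  ``lambdas`` is (m, k) (rows may be zero-padded).
    Returns tail probabilities and an error bound estimate.
    """
    L = np.atleast_2d(np.asarray(lambdas, dtype=float))
    qs = np.asarray(qs, dtype=float)
    m = L.shape[0]
    s = np.sqrt(2.0 * (L**2).sum(axis=1))
    if (s <= 0).any():
        raise ValueError("each eigenvalue set must contain a positive value")
    Ln = L / s[:, None]
    # beyond ~60 SDs the tail is < 1e-13, far below the absolute error
    # target; capping keeps the node count (and memory) bounded
    qn = np.minimum(qs / s, 60.0)

    # grid spacing from the aliasing requirement: images sit at q +- 2*pi*j/h
    r_alias = 0.0
    for i in range(m):
        lam_i = Ln[i][Ln[i] > 0]
        x_req = _chernoff_cutoff(lam_i, acc / 4.0)
        # upper images need q + R beyond the tail cutoff; lower images
        # vanish once q - R is below the support
        r_alias = max(r_alias, x_req - qn[i], qn[i])
    r_alias += 8.0 * _SMOOTH_TAU  # widening from the smoothing Gaussian
    h = 2.0 * np.pi / r_alias
    u_max = np.sqrt(2.0 * np.log(4.0 / acc)) / (_SMOOTH_TAU * 2.0**-1.5)
    n_nodes = int(np.ceil(u_max / h))
    u = (np.arange(1, n_nodes + 1) - 0.5) * h  # (N,)

    theta = -0.5 * qn[:, None] * u[None, :]
    log_rho = np.zeros((m, u.size))
    for k in range(Ln.shape[1]):
        lu = Ln[:, k][:, None] * u[None, :]
        theta += 0.5 * np.arctan(lu)
        log_rho += 0.25 * np.log1p(lu * lu)
    base = np.sin(theta) * np.exp(-log_rho) / u[None, :]

    taus = _SMOOTH_TAU * 2.0 ** (-0.5 * np.arange(4))
    p_tau = [
        0.5 + (h / np.pi) * (base * np.exp(-0.5 * (t * u) ** 2)[None, :]).sum(axis=1)
        for t in taus
    ]

    def richardson(p1, p2, p3):
        # quadratic in tau^2 through scales (t, t/2, t/4), evaluated at 0
        return p1 / 3.0 - 2.0 * p2 + (8.0 / 3.0) * p3

    p_coarse = richardson(p_tau[0], p_tau[1], p_tau[2])
    p_fine = richardson(p_tau[1], p_tau[2], p_tau[3])
    # two O(tau^6) extrapolations at successive scales: their difference
    # estimates the residual and flags the support-boundary bias near q = 0
    err = acc + 2.0 * np.abs(p_fine - p_coarse)
    return p_fine, err


def _liu_params(lambdas: np.ndarray) -> tuple[float, float, float, float, float]:
    """Four-moment match of the mixture to a noncentral chi-square.

    Returns (muQ, sigmaQ, df l, noncentrality d, muX) following the modified
    moment-matching rule that matches kurtosis when possible.
    """
    lam = np.asarray(lambdas, dtype=float)
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        l = a**2 - 2 * d
    else:
        l = 1.0 / s2
        a = np.sqrt(l)
        d = 0.0
    muQ = c1
    sigmaQ = np.sqrt(2.0 * c2)
    muX = l + d
    return muQ, sigmaQ, l, d, muX


def _liu_tail(lambdas: np.ndarray, q: float) -> float:
    muQ, sigmaQ, l, d, muX = _liu_params(lambdas)
    sigmaX = np.sqrt(2.0 * (l + 2.0 * d))
    x = (q - muQ) / sigmaQ * sigmaX + muX
    return float(stats.ncx2.sf(x, df=l, nc=d))


def _liu_quantile(lambdas: np.ndarray, tail_prob: float) -> float:
    """Upper-tail quantile of the mixture via the four-moment match."""
    muQ, sigmaQ, l, d, muX = _liu_params(lambdas)
    sigmaX = np.sqrt(2.0 * (l + 2.0 * d))
    x = stats.ncx2.isf(tail_prob, df=l, nc=d)
    return float((x - muX) / sigmaX * sigmaQ + muQ)


def _liu_quantiles(lam_sets: list[np.ndarray], tail_prob: float) -> np.ndarray:
    """Vectorized four-moment quantiles across several mixtures."""
    params = np.array([_liu_params(ls) for ls in lam_sets])
    muQ, sigmaQ, l, d, muX = params.T
    sigmaX = np.sqrt(2.0 * (l + 2.0 * d))
    x = stats.ncx2.isf(tail_prob, df=l, nc=d)
    return (x - muX) / sigmaX * sigmaQ + muQ


def _ruben_tail(lambdas: np.ndarray, q: float, tol: float = 1e-10,
                max_terms: int = 5000) -> float | None:
    """Tail probability via Ruben's series of central chi-square CDFs.

    P(Q <= q) = sum_k c_k F_chi2(q / beta; df = k0 + 2k) with beta below the
    smallest eigenvalue; all coefficients are positive and sum to one, so
    the truncation error is bounded by the unused coefficient mass.  Exact
    and fast near the support boundary (small q), where CF inversion and
    moment matching are weakest; returns None when the series converges too
    slowly (widely spread eigenvalues).
    """
    lam = np.asarray(lambdas, dtype=float)
    k0 = lam.size
    beta = 0.90625 * lam.min()
    r = 1.0 - beta / lam  # in [0, 1)
    c = np.empty(max_terms)
    h = np.empty(max_terms)
    c[0] = np.exp(0.5 * np.log(beta / lam).sum())
    mass = c[0]
    r_pow = np.ones_like(r)
    n_terms = max_terms
    for k in range(1, max_terms):
        r_pow *= r
        h[k] = 0.5 * r_pow.sum()
        c[k] = np.dot(c[:k][::-1], h[1 : k + 1]) / k
        mass += c[k]
        if 1.0 - mass < tol:
            n_terms = k + 1
            break
    else:
        return None
    dfs = k0 + 2.0 * np.arange(n_terms)
    cdf = float(np.dot(c[:n_terms], stats.chi2.cdf(q / beta, df=dfs)))
    return float(np.clip(1.0 - cdf, 0.0, 1.0))


def _saddlepoint_tail(lambdas: np.ndarray, q: float) -> float | None:
    """Lugannani-Rice saddlepoint tail for the chi-square mixture.

    Accurate to small relative error across the whole support, including
    near the boundary where moment matching fails; returns None close to
    the mean, where the saddlepoint is singular and moment matching is at
    its best anyway.
    """
    from scipy.optimize import brentq

    lam = np.asarray(lambdas, dtype=float)
    mean = lam.sum()
    if abs(q - mean) < 1e-4 * max(mean, 1e-300):
        return None

    def kprime(t):
        return float(np.sum(lam / (1.0 - 2.0 * lam * t)))

    hi = (1.0 - 1e-10) / (2.0 * lam.max())
    if q > mean:
        lo = 0.0
        while kprime(hi) < q:  # pragma: no cover - kprime diverges at hi
            hi = (hi + 1.0 / (2.0 * lam.max())) / 2.0
    else:
        lo = -1.0 / max(lam.min(), 1e-300)
        while kprime(lo) > q:
            lo *= 2.0
            if lo < -1e18:
                return None
        hi = 0.0
    t_hat = brentq(lambda t: kprime(t) - q, lo, hi, xtol=1e-14)
    K = -0.5 * float(np.log1p(-2.0 * lam * t_hat).sum())
    K2 = float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * lam * t_hat) ** 2))
    arg = 2.0 * (t_hat * q - K)
    if arg <= 0 or K2 <= 0:
        return None
    w = np.sign(t_hat) * np.sqrt(arg)
    u = t_hat * np.sqrt(K2)
    if abs(w) < 1e-5 or abs(u) < 1e-12:
        return None
    p = stats.norm.sf(w) - stats.norm.pdf(w) * (1.0 / w - 1.0 / u)
    return float(np.clip(p, 0.0, 1.0))


def pvalue_quadform(
    eigenvalues: np.ndarray, q: float, tol: float = 1e-6
) -> tuple[float, str]:
    """Tail probability P(sum lambda_k chi^2_{1} > q) with backend record.

    Primary backend is characteristic-function inversion; when its error
    bound exceeds ``tol`` (or the result falls outside [0, 1]) the
    four-moment approximation is used instead.  Returns (p, backend).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if not np.all(np.isfinite(lam)) or not np.isfinite(q):
        raise ValueError("non-finite input to pvalue_quadform")
    if (lam < 0).any():
        raise ValueError("eigenvalues must be nonnegative")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("eigenvalues must not all be zero")
    if q <= 0:
        return 1.0, "exact-mixture"
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], df=1)), "exact-mixture"
    p, err = _imhof_tail_many(lam[None, :], np.array([q]))
    p = float(p[0])
    if err[0] <= tol and -1e-12 <= p <= 1 + 1e-12:
        return float(np.clip(p, 0.0, 1.0)), "exact-mixture"
    p_ruben = _ruben_tail(lam, q, max_terms=1000)
    if p_ruben is not None:
        return p_ruben, "exact-mixture"
    return _fallback_tail(lam, q), "moment-approx"


def _fallback_tail(lam: np.ndarray, q: float) -> float:
    """Best uncertified tail: saddlepoint where defined, else moment match."""
    p = _saddlepoint_tail(lam, q)
    return p if p is not None else _liu_tail(lam, q)


# ---------------------------------------------------------------------------
# The optimal test
# ---------------------------------------------------------------------------

@dataclass
class RegionTestResult:
    """Outcome of one gene-/window-level association test."""

    unit_id: str
    q1: int
    q2: int
    statistic: float
    rho: float
    p_value: float
    method: str
    backend: str
    rho_pvalues: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho {self.rho} outside [0, 1]")


def _rho_sqrt(rho: float, p: int) -> np.ndarray:
    """Symmetric square root of R_rho = (1-rho) I + rho 11' (p x p)."""
    a = np.sqrt(1.0 - rho)
    b = (np.sqrt(1.0 - rho + rho * p) - a) / p
    return a * np.eye(p) + b * np.ones((p, p))


def q_statistic(
    matrix: CombinedGeneMatrix | np.ndarray,
    null: NullModel,
    weights: np.ndarray,
    rho: float,
) -> float:
    """Q_rho = (y-mu)' G W R_rho W G' (y-mu) for one mixing parameter."""
    G = matrix.values if isinstance(matrix, CombinedGeneMatrix) else np.asarray(matrix)
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must lie in [0, 1]")
    S = np.asarray(weights) * null.score(G)
    return float((1.0 - rho) * np.sum(S**2) + rho * np.sum(S) ** 2)


def _eig_lambdas(M: np.ndarray) -> np.ndarray:
    lam = np.linalg.eigvalsh((M + M.T) / 2.0)
    thresh = max(1e-12, 1e-10 * max(lam.max(initial=0.0), 0.0))
    return lam[lam > thresh]


def _mixture_tails(lam_sets: list[np.ndarray], qs: np.ndarray, tol: float):
    """Batch tail probabilities across mixtures; per-element fallbacks.

    Single-eigenvalue rows use the exact scaled chi-square tail; the rest go
    through CF inversion with a Liu-type fallback when the error bound is
    not met.
    """
    out = np.empty(len(lam_sets))
    backends = [""] * len(lam_sets)
    multi = [i for i, l in enumerate(lam_sets) if l.size > 1]
    for i, l in enumerate(lam_sets):
        if l.size == 1:
            out[i] = 1.0 if qs[i] <= 0 else float(stats.chi2.sf(qs[i] / l[0], df=1))
            backends[i] = "exact-mixture"
    if multi:
        kmax = max(lam_sets[i].size for i in multi)
        L = np.zeros((len(multi), kmax))
        for r, i in enumerate(multi):
            L[r, : lam_sets[i].size] = lam_sets[i]
        ps, err = _imhof_tail_many(L, qs[multi])
        for r, i in enumerate(multi):
            p = ps[r]
            if err[r] <= tol and -1e-9 <= p <= 1 + 1e-9:
                out[i] = float(np.clip(p, 0.0, 1.0))
                backends[i] = "exact-mixture"
                continue
            out[i] = _fallback_tail(lam_sets[i], float(qs[i]))
            backends[i] = "moment-approx"
    return out, backends


# Gauss-Legendre nodes for the outer integral over the burden chi-square
# component, after the substitution x = t^2 that removes the density's
# square-root singularity at zero.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)
_T_UPPER = np.sqrt(60.0)
_T_NODES = 0.5 * _T_UPPER * (_GL_NODES + 1.0)
_T_WEIGHTS = 0.5 * _T_UPPER * _GL_WEIGHTS


def _skat_o_pvalue(
    A: np.ndarray,
    rho_pvals: np.ndarray,
    rho_grid: np.ndarray,
    lam_sets: list[np.ndarray],
    tol: float,
) -> tuple[float, str]:
    """Min-p combination over the rho grid (one-dimensional integration).

    Decomposes the projected score kernel A into its component along the
    column-mean direction (the burden axis, a scaled 1-df chi-square eta)
    and the orthogonal remainder kappa; the final p-value is
    1 - P(Q_rho(eta, kappa) below each rho's T-quantile for all rho),
    integrated over eta.
    """
    T = float(rho_pvals.min())
    m = len(rho_grid)
    ones = np.ones(A.shape[0])
    A1 = A @ ones
    denom = float(ones @ A1) / A.shape[0] ** 2  # z_bar' z_bar
    if denom <= 1e-14 * max(np.trace(A), 1e-300):
        return min(1.0, T * m), "moment-approx"
    cof = (A1 / A.shape[0]) / denom  # projections of columns on z_bar
    Phi = A - np.outer(cof, cof) * denom  # remainder kernel
    lam = _eig_lambdas(Phi)
    if lam.size == 0:
        # rank-1 kernel: all rho give the same 1-df test
        return T, "exact-mixture"
    p_m = A.shape[0]
    muQ = lam.sum()
    var_remain = 4.0 * denom * float(cof @ Phi @ cof)
    varQ = 2.0 * np.sum(lam**2) + var_remain
    tau = (p_m**2 * rho_grid + (1.0 - rho_grid) * np.sum(cof**2)) * denom

    # per-rho quantiles of Q_rho at tail T (four-moment quantiles)
    qmin = _liu_quantiles(lam_sets, T)

    rho_c = np.minimum(rho_grid, 0.999)
    x = _T_NODES**2  # eta ~ chi^2_1 values
    # minimum over rho of the kappa-threshold implied by each quantile
    thr = (qmin[None, :] - tau[None, :] * x[:, None]) / (1.0 - rho_c[None, :])
    thr_min = thr.min(axis=1)
    # variance-rescale the remainder to account for the dropped cross term
    sd_adj = np.sqrt(max(varQ - var_remain, 1e-300) / varQ)
    thr_std = (thr_min - muQ) * sd_adj + muQ

    tails = np.empty(x.size)
    pos = thr_std > 0
    backend = "exact-mixture"
    if pos.any():
        if lam.size == 1:
            t_tails = stats.chi2.sf(thr_std[pos] / lam[0], df=1)
            t_err = np.zeros(int(pos.sum()))
        else:
            t_tails, t_err = _imhof_tail_many(
                np.broadcast_to(lam, (int(pos.sum()), lam.size)), thr_std[pos]
            )
        bad = (t_err > 1e-5) | (t_tails < -1e-6) | (t_tails > 1 + 1e-6)
        if bad.any():
            # near-boundary thresholds: switch those rows to the
            # saddlepoint/moment fallback chain
            t_tails = np.array(t_tails, dtype=float)
            for j in np.where(bad)[0]:
                t_tails[j] = _fallback_tail(lam, float(thr_std[pos][j]))
        tails[pos] = np.clip(t_tails, 0.0, 1.0)
    tails[~pos] = 1.0

    dens = np.sqrt(2.0 / np.pi) * np.exp(-x / 2.0)  # chi^2_1 density * 2t
    prob_all_accept = float(np.sum(_T_WEIGHTS * (1.0 - tails) * dens))
    p = 1.0 - prob_all_accept
    p = min(p, T * m)  # Bonferroni guard for numerically degenerate cases
    if p <= 0.0 or not np.isfinite(p):
        p = min(1.0, T * m)
        backend = "moment-approx"
    return float(min(max(p, 0.0), 1.0)), backend


def skat_o(
    matrix: CombinedGeneMatrix,
    null: NullModel,
    config: TestConfig | None = None,
) -> RegionTestResult:
    """Optimal combined-matrix region test over the rho grid.

    Computes p_rho for every rho in the grid, takes T = min_rho p_rho, and
    corrects for the minimization by integrating the joint null of the
    burden and variance-component parts.  A single-element grid reduces to
    that rho's test; an all-constant matrix yields p = 1 with a warning.
    """
    config = config or TestConfig()
    if matrix.is_empty:
        raise ValueError(f"{matrix.unit_id}: empty marker matrix")
    if len(matrix.sample_ids) != null.n_samples:
        raise ValueError("matrix and null model sample counts differ")
    G = matrix.values
    w = region_weights(matrix, config)
    S = w * null.score(G)
    A = w[:, None] * null.gram(G) * w[None, :]

    if np.trace(A) <= 1e-14:
        warnings.warn(f"{matrix.unit_id}: all marker columns constant; p = 1")
        return RegionTestResult(
            matrix.unit_id, matrix.q1, matrix.q2, 0.0, 0.0, 1.0, "skat-o", "degenerate"
        )

    grid = np.asarray(config.rho_grid, dtype=float)
    p_cols = G.shape[1]
    qs = np.array(
        [(1.0 - r) * np.sum(S**2) + r * np.sum(S) ** 2 for r in grid]
    )
    lam_sets = []
    for r in grid:
        Rh = _rho_sqrt(r, p_cols)
        lam_sets.append(_eig_lambdas(Rh @ A @ Rh))
    rho_pvals, backends = _mixture_tails(lam_sets, qs, config.pvalue_tol)

    i_best = int(np.argmin(rho_pvals))  # ties break toward smaller rho
    rho_opt = float(grid[i_best])
    stat = float(qs[i_best])
    rho_map = {float(r): float(p) for r, p in zip(grid, rho_pvals)}

    if grid.size == 1 or p_cols == 1:
        # single rho, or a rank-1 region where all rho coincide
        return RegionTestResult(
            matrix.unit_id,
            matrix.q1,
            matrix.q2,
            stat,
            rho_opt,
            float(rho_pvals[i_best]),
            "skat-o",
            backends[i_best],
            rho_map,
        )

    p_final, backend = _skat_o_pvalue(A, rho_pvals, grid, lam_sets, config.pvalue_tol)
    return RegionTestResult(
        matrix.unit_id,
        matrix.q1,
        matrix.q2,
        stat,
        rho_opt,
        p_final,
        "skat-o",
        backend,
        rho_map,
    )


def test_unit(
    matrix: CombinedGeneMatrix,
    null: NullModel,
    config: TestConfig | None = None,
    method: str = "skat-o",
) -> RegionTestResult:
    """Dispatch a region test: 'skat' (rho=0), 'burden' (rho=1) or 'skat-o'."""
    config = config or TestConfig()
    if method == "skat":
        cfg = TestConfig(config.beta_weight_params, config.cnv_weight, (0.0,), config.pvalue_tol)
    elif method == "burden":
        cfg = TestConfig(config.beta_weight_params, config.cnv_weight, (1.0,), config.pvalue_tol)
    elif method == "skat-o":
        cfg = config
    else:
        raise ValueError(f"unknown method {method!r}")
    res = skat_o(matrix, null, cfg)
    res.method = method
    return res
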