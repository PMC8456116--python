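"""Null model, quadratic-form p-values, and the optimal region test."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from inco.genomic_data import CombinedGeneMatrix
from inco.region_test import (
    NullFitError,
    TestConfig,
    fit_null,
    pvalue_quadform,
    q_statistic,
    region_weights,
    skat_o,
)
from inco.region_test import test_unit as dispatch_unit
from .conftest import make_matrix


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

def test_intercept_only_binary_means(balanced_binary_null):
    _, null = balanced_binary_null
    np.testing.assert_allclose(null.mu, 0.30, atol=1e-8)


def test_intercept_only_continuous_means(rng):
    y = rng.normal(2.0, 1.0, 50)
    null = fit_null(y, None, "continuous")
    np.testing.assert_allclose(null.mu, y.mean(), atol=1e-10)


def _newton_logistic(y, X, iters=50):
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        mu = expit(X @ beta)
        W = mu * (1 - mu)
        beta = beta + np.linalg.solve((X * W[:, None]).T @ X, X.T @ (y - mu))
    return expit(X @ beta)


def test_logistic_fit_matches_newton_oracle(rng):
    n = 60
    z = rng.normal(size=(n, 2))
    y = (rng.random(n) < expit(0.3 + z @ [0.8, -0.5])).astype(float)
    null = fit_null(y, z, "binary")
    X = np.column_stack([np.ones(n), z])
    np.testing.assert_allclose(null.mu, _newton_logistic(y, X), atol=1e-8)


def test_rank_deficiency_names_columns(rng):
    z = rng.normal(size=(30, 2))
    z = np.column_stack([z, z[:, 0]])  # duplicate column
    y = (rng.random(30) < 0.4).astype(float)
    with pytest.raises(NullFitError, match="column"):
        fit_null(y, z, "binary")


def test_missing_phenotype_rejected():
    with pytest.raises(ValueError):
        fit_null(np.array([0.0, np.nan, 1.0]), None, "binary")


# ---------------------------------------------------------------------------
# Q statistic
# ---------------------------------------------------------------------------

def test_single_column_q_constant_in_rho(rng, balanced_binary_null):
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=1, q2=0)
    w = np.ones(1)
    qs = [q_statistic(m, null, w, r) for r in (0.0, 0.3, 1.0)]
    assert max(qs) - min(qs) < 1e-12


def test_burden_identity_at_rho_one(rng, balanced_binary_null):
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=3, q2=2)
    w = rng.uniform(0.5, 2.0, 5)
    S = w * (m.values.T @ null.resid)
    assert q_statistic(m, null, w, 1.0) == pytest.approx(S.sum() ** 2, rel=1e-12)


def test_q_matches_dense_quadratic_form(rng, balanced_binary_null):
    _, null = balanced_binary_null
    for _ in range(5):
        G = rng.normal(size=(100, 5))
        w = rng.uniform(0.2, 2.0, 5)
        rho = float(rng.random())
        R = (1 - rho) * np.eye(5) + rho * np.ones((5, 5))
        M = G @ np.diag(w) @ R @ np.diag(w) @ G.T
        expected = float(null.resid @ M @ null.resid)
        assert q_statistic(G, null, w, rho) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# Chi-square mixture tails
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "lam,q",
    [([1.0], 3.841459), ([1.0, 1.0], 5.991465)],
)
def test_quadform_chi_square_quantiles(lam, q):
    p, _ = pvalue_quadform(np.array(lam), q)
    assert p == pytest.approx(0.0500, abs=5e-5)


def test_quadform_matches_monte_carlo(rng):
    for k in (2, 3, 4):
        lam = rng.uniform(0.1, 3.0, k)
        q = float(lam.sum() + 2.0 * np.sqrt(2 * (lam**2).sum()))
        p, backend = pvalue_quadform(lam, q)
        draws = rng.chisquare(1, (1_000_000, k)) @ lam
        p_mc = (draws > q).mean()
        se = np.sqrt(p_mc * (1 - p_mc) / draws.shape[0])
        assert abs(p - p_mc) < 3 * se + 1e-12, (lam, backend)


def test_quadform_monotone_in_q(rng):
    lam = np.array([2.0, 1.0, 0.3])
    qs = np.linspace(0.1, 30.0, 40)
    ps = [pvalue_quadform(lam, q)[0] for q in qs]
    assert all(a >= b - 1e-9 for a, b in zip(ps, ps[1:]))


def test_quadform_rejects_bad_input():
    with pytest.raises(ValueError):
        pvalue_quadform(np.array([np.nan]), 1.0)
    with pytest.raises(ValueError):
        pvalue_quadform(np.array([0.0, 0.0]), 1.0)


# ---------------------------------------------------------------------------
# Optimal test
# ---------------------------------------------------------------------------

def _perm_pvalue(m, y, kind, rho, n_perm, seed, config):
    """Permutation distribution of Q_rho under an intercept-only null."""
    null = fit_null(y, None, kind)
    w = region_weights(m, config)
    G = m.values
    q_obs = q_statistic(m, null, w, rho)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    S = (perms - y.mean()) @ G * w[None, :]  # residuals under permuted labels
    q_perm = (1 - rho) * (S**2).sum(axis=1) + rho * S.sum(axis=1) ** 2
    return (1 + (q_perm >= q_obs).sum()) / (1 + n_perm)


def test_single_rho_agrees_with_permutation_oracle(rng):
    # continuous trait: the chi-square-mixture null is exact up to
    # asymptotics free of the binary small-sample moment effect
    config = TestConfig()
    y = rng.normal(size=100)
    null = fit_null(y, None, "continuous")
    for rho in (0.0, 0.5, 1.0):
        m = make_matrix(rng, n=100, q1=4, q2=2)
        res = skat_o(m, null, dataclasses.replace(config, rho_grid=(rho,)))
        n_perm = 4000
        p_perm = _perm_pvalue(m, y, "continuous", rho, n_perm, 7, config)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) < 3 * se + 0.01, rho


def test_one_column_equals_score_test(rng, balanced_binary_null):
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=1, q2=0)
    res = skat_o(m, null)
    g = m.values[:, 0]
    q = (g @ null.resid) ** 2
    lam = null.gram(g.reshape(-1, 1)).item()
    p_score = stats.chi2.sf(q / lam, df=1)
    assert res.p_value == pytest.approx(p_score, abs=1e-6)


def test_constant_matrix_yields_p_one(balanced_binary_null):
    _, null = balanced_binary_null
    m = make_matrix(np.random.default_rng(0), n=100, q1=1, q2=1)
    m.snv_block[:] = 2.0
    m.cnv_block[:] = 0
    with pytest.warns(UserWarning):
        res = skat_o(m, null)
    assert res.p_value == 1.0


def test_duplicated_column_burden_invariance(rng, balanced_binary_null):
    """Splitting a marker into two copies at half weight keeps the burden score."""
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=2, q2=0)
    w = np.ones(2)
    q_single = q_statistic(m.values[:, :1], null, np.ones(1), 1.0)
    dup = np.column_stack([m.values[:, 0], m.values[:, 0]])
    q_dup = q_statistic(dup, null, np.array([0.5, 0.5]), 1.0)
    assert q_dup == pytest.approx(q_single, rel=1e-12)


def test_dispatch_and_metadata(rng, balanced_binary_null):
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=3, q2=2)
    burden = dispatch_unit(m, null, method="burden")
    forced = skat_o(m, null, TestConfig(rho_grid=(1.0,)))
    assert burden.p_value == pytest.approx(forced.p_value, rel=1e-12)
    assert burden.q1 == 3 and burden.q2 == 2
    skat = dispatch_unit(m, null, method="skat")
    assert skat.rho == 0.0
    both = dispatch_unit(m, null, method="skat-o")
    assert 0.0 <= both.p_value <= 1.0


def test_empty_matrix_rejected(rng, balanced_binary_null):
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=0, q2=0)
    with pytest.raises(ValueError):
        dispatch_unit(m, null)


def test_cnv_weight_invariant_to_maf_bookkeeping(rng, balanced_binary_null):
    """CNV columns carry the flat weight regardless of their carrier rate."""
    _, null = balanced_binary_null
    m = make_matrix(rng, n=100, q1=0, q2=3)
    w = region_weights(m, TestConfig())
    np.testing.assert_array_equal(w, np.ones(3))
    w2 = region_weights(m, TestConfig(cnv_weight=2.0))
    np.testing.assert_array_equal(w2, np.full(3, 2.0))


def test_continuous_null_skat_o_calibration(rng):
    """Null p-values stay roughly uniform for a continuous trait."""
    y = rng.normal(size=150)
    null = fit_null(y, None, "continuous")
    ps = []
    for _ in range(150):
        m = make_matrix(rng, n=150, q1=4, q2=2)
        ps.append(skat_o(m, null).p_value)
    assert stats.kstest(ps, "uniform").pvalue > 0.01
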