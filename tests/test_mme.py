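import numpy as np
import pytest
from scipy.linalg import block_diag

from orchardblup.mme import (Ar1Residual, IidResidual, MixedModel,
                             MixedModelError, RandomTerm, SitewiseResidual,
                             ar1_matrix, reml_fit, solve_mme,
                             spatial_residual_cov)


def test_ar1_matrix_values_and_domain():
    assert np.allclose(ar1_matrix(0.0, 4), np.eye(4))
    expected = [[1, .5, .25], [.5, 1, .5], [.25, .5, 1]]
    assert np.allclose(ar1_matrix(0.5, 3), expected)
    with pytest.raises(MixedModelError):
        ar1_matrix(1.0, 3)
    with pytest.raises(MixedModelError):
        ar1_matrix(0.5, 0)


def test_ar1_inverse_is_tridiagonal():
    inv = np.linalg.inv(ar1_matrix(0.7, 6))
    off = np.triu(inv, k=2)
    assert np.max(np.abs(off)) < 1e-10


def test_spatial_cov_hand_kronecker():
    layout = [(1, 1), (1, 2), (2, 1), (2, 2)]
    cov = spatial_residual_cov(1.0, 0.0, 0.5, 0.5, layout)
    # shared row or column -> 0.5; diagonal neighbour -> 0.25
    assert cov[0, 1] == pytest.approx(0.5)
    assert cov[0, 2] == pytest.approx(0.5)
    assert cov[0, 3] == pytest.approx(0.25)
    assert np.allclose(np.diag(cov), 1.0)
    with pytest.raises(MixedModelError, match="duplicate"):
        spatial_residual_cov(1.0, 0.0, 0.5, 0.5, [(1, 1), (1, 1)])


def test_spatial_cov_rho_zero_is_diagonal():
    cov = spatial_residual_cov(2.0, 3.0, 0.0, 0.0, [(1, 1), (2, 5), (3, 2)])
    assert np.allclose(cov, 5.0 * np.eye(3))


def test_spatial_cov_matches_explicit_kronecker_on_full_grid():
    rows, cols, rc, rr = 5, 5, 0.6, 0.3
    layout = [(r, c) for r in range(rows) for c in range(cols)]
    cov = spatial_residual_cov(1.7, 0.0, rc, rr, layout)
    kron = 1.7 * np.kron(ar1_matrix(rr, rows), ar1_matrix(rc, cols))
    assert np.allclose(cov, kron, atol=1e-10)


def _oneway(seed=1, k=15, r=6, s2u=2.0, s2e=1.0):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(s2u), k)
    y = np.repeat(u, r) + rng.normal(0, np.sqrt(s2e), k * r) + 5.0
    groups = np.repeat(np.arange(k), r)
    X = np.ones((k * r, 1))
    term = RandomTerm("u", groups, None, k)
    return y, X, term, groups, k, r


def test_reml_equals_anova_on_balanced_oneway():
    y, X, term, groups, k, r = _oneway()
    fit = reml_fit(MixedModel(y, X, {"u": term}, IidResidual(len(y))))
    msb = r * np.sum((y.reshape(k, r).mean(1) - y.mean()) ** 2) / (k - 1)
    msw = np.sum((y.reshape(k, r) - y.reshape(k, r).mean(1)[:, None]) ** 2) \
        / (k * (r - 1))
    assert fit.converged
    assert fit.varcomp["u"]["variances"][0] == pytest.approx((msb - msw) / r,
                                                             abs=1e-6)
    assert fit.varcomp["residual"]["variances"][0] == pytest.approx(msw,
                                                                    abs=1e-6)


def test_restricted_loglik_matches_bruteforce_formula():
    y, X, term, *_ = _oneway(seed=2, k=10, r=5)
    mm = MixedModel(y, X, {"u": term}, IidResidual(len(y)))
    fit = mm.reml()
    V = mm._build_V(fit.theta)
    Vi = np.linalg.inv(V)
    C = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(C) @ X.T @ Vi
    ll = -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(C)[1] + y @ P @ y)
    assert fit.loglik == pytest.approx(ll, abs=1e-6)


def test_gls_limit_without_random_terms():
    rng = np.random.default_rng(3)
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = X @ [2.0, -1.0] + rng.normal(0, 0.5, n)
    fit = solve_mme(MixedModel(y, X, {}, IidResidual(n)),
                    {"residual": {"variances": [0.25]}})
    beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
    assert np.allclose(fit.beta, beta_ols, atol=1e-10)


def test_blups_shrink_to_zero_as_variance_vanishes():
    y, X, term, groups, k, r = _oneway(seed=4)
    mm = MixedModel(y, X, {"u": term}, IidResidual(len(y)))
    fit = mm.solve({"u": {"variances": [1e-12]},
                    "residual": {"variances": [1.0]}})
    u, _ = mm.predict_random(fit, "u", np.arange(k))
    assert np.max(np.abs(u)) < 1e-6


def test_blups_equal_closed_form_shrunken_family_means():
    # balanced 4 sires x 10 progeny with known variance components
    rng = np.random.default_rng(5)
    k, r, s2u, s2e = 4, 10, 3.0, 2.0
    u = rng.normal(0, np.sqrt(s2u), k)
    y = np.repeat(u, r) + rng.normal(0, np.sqrt(s2e), k * r) + 8.0
    groups = np.repeat(np.arange(k), r)
    mm = MixedModel(y, np.ones((k * r, 1)),
                    {"u": RandomTerm("u", groups, None, k)},
                    IidResidual(k * r))
    fit = mm.solve({"u": {"variances": [s2u]},
                    "residual": {"variances": [s2e]}})
    uhat, pev = mm.predict_random(fit, "u", np.arange(k))
    w = r * s2u / (r * s2u + s2e)
    mu = y.reshape(k, r).mean(1).mean()  # balanced GLS intercept
    closed = w * (y.reshape(k, r).mean(1) - mu)
    assert np.allclose(uhat, closed, atol=1e-8)
    assert np.all(pev >= 0) and np.all(pev <= s2u + 1e-10)


def test_blup_invariant_to_observation_reordering():
    y, X, term, groups, k, r = _oneway(seed=6)
    mm = MixedModel(y, X, {"u": term}, IidResidual(len(y)))
    vc = {"u": {"variances": [2.0]}, "residual": {"variances": [1.0]}}
    u1, _ = mm.predict_random(mm.solve(vc), "u", np.arange(k))
    perm = np.random.default_rng(0).permutation(len(y))
    mm2 = MixedModel(y[perm], X[perm],
                     {"u": RandomTerm("u", groups[perm], None, k)},
                     IidResidual(len(y)))
    u2, _ = mm2.predict_random(mm2.solve(vc), "u", np.arange(k))
    assert np.allclose(u1, u2, atol=1e-10)


def test_pev_of_unrelated_unphenotyped_individual_is_full_variance():
    # K has an extra founder never observed: PEV = (1+F) sigma2_a, accuracy 0
    K = np.eye(5)
    levels = np.array([0, 1, 2, 3])  # individual 4 unobserved
    rng = np.random.default_rng(7)
    y = rng.normal(10, 1, 4)
    mm = MixedModel(y, np.ones((4, 1)),
                    {"a": RandomTerm("a", levels, K, 5)}, IidResidual(4))
    fit = mm.solve({"a": {"variances": [2.5]},
                    "residual": {"variances": [1.0]}})
    u, pev = mm.predict_random(fit, "a", np.array([4]))
    assert u[0] == pytest.approx(0.0, abs=1e-12)
    assert pev[0] == pytest.approx(2.5, abs=1e-9)


def test_boundary_variance_is_floored_and_flagged():
    rng = np.random.default_rng(8)
    k, r = 12, 6
    y = rng.normal(5, 1.0, k * r)
    groups = np.repeat(np.arange(k), r)
    # remove group means entirely: between-group variance below expectation,
    # so the REML group variance is pinned at the boundary floor
    y = y - y.reshape(k, r).mean(1)[groups] + 5.0
    mm = MixedModel(y, np.ones((k * r, 1)),
                    {"u": RandomTerm("u", groups, None, k)},
                    IidResidual(k * r))
    fit = mm.reml()
    assert fit.varcomp["u"]["variances"][0] < 1e-6
    assert any("u:var" in b for b in fit.boundary)


def test_rank_deficient_fixed_design_names_aliased_term():
    n = 20
    X = np.column_stack([np.ones(n), np.ones(n)])
    with pytest.raises(MixedModelError, match="aliased"):
        MixedModel(np.zeros(n), X, {}, IidResidual(n),
                   fixed_names=["intercept", "dup"])


def test_sitewise_residual_recovers_heterogeneous_variances():
    rng = np.random.default_rng(9)
    site = np.repeat([0, 1], 150)
    y = np.concatenate([rng.normal(0, 1.0, 150), rng.normal(0, 3.0, 150)])
    mm = MixedModel(y, np.ones((300, 1)), {},
                    SitewiseResidual(site, 2, ["a", "b"]))
    fit = mm.reml()
    v = fit.varcomp["residual"]["variances"]
    assert v[0] == pytest.approx(1.0, rel=0.35)
    assert v[1] == pytest.approx(9.0, rel=0.35)


def test_kron_term_unstructured_covariance_recovery():
    # two groups sharing levels through a known K: check Sigma recovery
    rng = np.random.default_rng(10)
    m, reps = 80, 4
    Sig = np.array([[2.0, 1.0], [1.0, 2.0]])
    L = np.linalg.cholesky(Sig)
    u = rng.standard_normal((m, 2)) @ L.T
    levels = np.tile(np.repeat(np.arange(m), reps), 2)
    groups = np.repeat([0, 1], m * reps)
    y = u[levels % m][np.arange(len(levels)), groups] \
        + rng.normal(0, 1.0, len(levels))
    term = RandomTerm("u", levels, None, m, groups=groups, n_groups=2,
                      group_names=["g0", "g1"])
    mm = MixedModel(y, np.ones((len(y), 1)), {"u": term},
                    SitewiseResidual(groups, 2))
    fit = mm.reml()
    S = fit.varcomp["u"]["Sigma"]
    corr = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
    # REML tracks the realized (co)variance of this draw of u
    real = np.cov(u.T, ddof=1)
    real_corr = real[0, 1] / np.sqrt(real[0, 0] * real[1, 1])
    assert S[0, 0] == pytest.approx(real[0, 0], abs=0.5)
    assert S[1, 1] == pytest.approx(real[1, 1], abs=0.5)
    assert corr == pytest.approx(real_corr, abs=0.2)
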