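import numpy as np
import pytest

from hornpred import (
    HornpredError,
    MixedModelSpec,
    RandomTerm,
    aic_compare,
    fit_variance_components,
    liability_to_observed_h2,
    observed_to_liability_h2,
    solve_mme,
    variance_explained_by_marker,
)


def _random_psd(n, rng):
    B = rng.normal(size=(n, n))
    K = B @ B.T / n
    K /= np.mean(np.diag(K))
    return K


def _gls_oracle(y, X, covs, s2):
    """Explicit V-inversion GLS + BLUP oracle."""
    n = len(y)
    V = s2[-1] * np.eye(n)
    for C, s in zip(covs, s2[:-1]):
        V += s * C
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = Vi @ (y - X @ beta)
    return beta, r


# ---------------------------------------------------------------------------
# Henderson's equations
# ---------------------------------------------------------------------------


def test_mme_equals_explicit_gls_on_small_instance():
    rng = np.random.default_rng(1)
    n = 20
    K = _random_psd(n, rng)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    s2 = {"animal": 0.7, "residual": 0.4}
    spec = MixedModelSpec(y=y, X=X, fixed_names=["int", "x"],
                          random_terms=[RandomTerm("animal", Z=None, K=K)])
    sol = solve_mme(spec, s2, ridge=0.0)
    beta, Vir = _gls_oracle(y, X, [K], np.array([0.7, 0.4]))
    u = 0.7 * K @ Vir
    np.testing.assert_allclose(sol.beta, beta, atol=1e-8)
    np.testing.assert_allclose(sol.u["animal"], u, atol=1e-8)
    assert sol.residual_norm < 1e-8


def test_vanishing_variance_ratio_shrinks_blups_to_zero():
    rng = np.random.default_rng(2)
    n = 30
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    spec = MixedModelSpec(y=y, X=X, fixed_names=["int"],
                          random_terms=[RandomTerm("u", Z=None, K=np.eye(n))])
    sol = solve_mme(spec, {"u": 1e-9, "residual": 1.0})
    assert np.abs(sol.u["u"]).max() < 1e-6


def test_identity_k_matches_ridge_regression():
    rng = np.random.default_rng(3)
    n, q = 50, 4
    Z = rng.normal(size=(n, q))
    y = rng.normal(size=n)
    X = np.ones((n, 1))
    s2u, s2e = 0.5, 1.0
    spec = MixedModelSpec(y=y, X=X, fixed_names=["int"],
                          random_terms=[RandomTerm("u", Z=Z)])
    sol = solve_mme(spec, {"u": s2u, "residual": s2e})
    # closed-form joint ridge solve
    lam = s2e / s2u
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(q)]])
    sol2 = np.linalg.solve(C, np.concatenate([X.T @ y, Z.T @ y]))
    np.testing.assert_allclose(np.concatenate([sol.beta, sol.u["u"]]), sol2, atol=1e-8)


def test_confounded_fixed_columns_named():
    n = 20
    x = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), x, x])  # duplicate column
    spec = MixedModelSpec(y=np.random.default_rng(0).normal(size=n), X=X,
                          fixed_names=["int", "x1", "x1_copy"], random_terms=[])
    with pytest.raises(HornpredError, match="confounded"):
        solve_mme(spec, {"residual": 1.0})


# ---------------------------------------------------------------------------
# Variance components
# ---------------------------------------------------------------------------


def test_reml_matches_balanced_halfsib_anova():
    rng = np.random.default_rng(4)
    s, k = 40, 20
    sire_eff = rng.normal(0, np.sqrt(0.3), size=s)
    y = np.repeat(sire_eff, k) + rng.normal(0, np.sqrt(0.7), size=s * k)
    Z = np.kron(np.eye(s), np.ones((k, 1)))
    spec = MixedModelSpec(y=y, X=np.ones((s * k, 1)), fixed_names=["int"],
                          random_terms=[RandomTerm("sire", Z=Z)])
    fit = fit_variance_components(spec, method="REML")
    groups = y.reshape(s, k)
    msb = k * np.var(groups.mean(axis=1), ddof=1)
    msw = np.mean(np.var(groups, axis=1, ddof=1))
    anova_sire = (msb - msw) / k
    assert anova_sire > 0  # interior this seed
    assert fit.varcomps["sire"] == pytest.approx(anova_sire, abs=1e-6)
    assert fit.varcomps["residual"] == pytest.approx(msw, abs=1e-6)


def test_null_signal_hits_variance_boundary():
    rng = np.random.default_rng(5)
    hits = 0
    for seed in range(7):
        r = np.random.default_rng(seed)
        n = 200
        K = _random_psd(n, r)
        y = r.normal(size=n)  # no genetic signal
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), fixed_names=["int"],
                              random_terms=[RandomTerm("g", Z=None, K=K)])
        fit = fit_variance_components(spec, method="REML")
        if "g" in fit.boundary or fit.varcomps["g"] < 0.05 * fit.varcomps["residual"]:
            hits += 1
    assert hits >= 4


def test_ml_loglik_monotone_in_nested_models():
    rng = np.random.default_rng(6)
    n = 150
    d = rng.integers(0, 3, size=n).astype(float)
    y = 0.4 * d + rng.normal(size=n)
    X = np.ones((n, 1))
    f1 = fit_variance_components(
        MixedModelSpec(y=y, X=X, fixed_names=["int"],
                       random_terms=[RandomTerm("alpha", Z=d)]), method="ML")
    f2 = fit_variance_components(
        MixedModelSpec(y=y, X=X, fixed_names=["int"],
                       random_terms=[RandomTerm("alpha", Z=d),
                                     RandomTerm("delta", Z=(d == 1).astype(float))]),
        method="ML")
    assert f2.loglik_ml >= f1.loglik_ml - 1e-3  # up to optimiser tolerance
    assert f1.aic == pytest.approx(-2 * f1.loglik_ml + 2 * f1.n_params)


def test_aic_compare_table_semantics():
    rng = np.random.default_rng(7)
    n = 100
    y = rng.normal(size=n)
    spec = MixedModelSpec(y=y, X=np.ones((n, 1)), fixed_names=["int"],
                          random_terms=[RandomTerm("u", Z=rng.normal(size=n))])
    fit = fit_variance_components(spec, method="ML")
    table = aic_compare([fit, fit], labels=["null", "dup"])
    assert table["delta_aic"].tolist() == [0.0, 0.0]
    assert table["best"].tolist() == [True, False]  # tie goes to first


def test_aic_compare_rejects_reml_across_fixed_structures():
    rng = np.random.default_rng(8)
    n = 60
    y = rng.normal(size=n)
    x = rng.normal(size=n)
    f1 = fit_variance_components(
        MixedModelSpec(y=y, X=np.ones((n, 1)), fixed_names=["int"],
                       random_terms=[RandomTerm("u", Z=x)]), method="REML")
    f2 = fit_variance_components(
        MixedModelSpec(y=y, X=np.column_stack([np.ones(n), x]),
                       fixed_names=["int", "x"],
                       random_terms=[RandomTerm("u", Z=x)]), method="REML")
    with pytest.raises(HornpredError, match="REML"):
        aic_compare([f1, f2])


def test_useless_extra_parameter_costs_about_two_aic():
    deltas = []
    for seed in range(200):
        rng = np.random.default_rng(1000 + seed)
        n = 120
        d = rng.integers(0, 3, size=n).astype(float)
        y = rng.normal(size=n)  # marker has no effect
        X = np.ones((n, 1))
        f1 = fit_variance_components(
            MixedModelSpec(y=y, X=X, fixed_names=["int"],
                           random_terms=[RandomTerm("alpha", Z=d)]), method="ML")
        f2 = fit_variance_components(
            MixedModelSpec(y=y, X=X, fixed_names=["int"],
                           random_terms=[RandomTerm("alpha", Z=d),
                                         RandomTerm("delta", Z=(d == 1).astype(float))]),
            method="ML")
        deltas.append(f2.aic - f1.aic)
    # AIC penalty 2 minus a (boundary-constrained) chi2_1 improvement
    assert 0.5 <= np.mean(deltas) <= 2.0


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def test_variance_explained_extremes():
    rng = np.random.default_rng(9)
    n = 400
    d = rng.integers(0, 3, size=n).astype(float)
    # null marker
    y = rng.normal(size=n)
    spec = MixedModelSpec(y=y, X=np.ones((n, 1)), fixed_names=["int"],
                          random_terms=[RandomTerm("alpha", Z=d)])
    fit = fit_variance_components(spec, method="ML")
    assert variance_explained_by_marker(fit, y, ["alpha"])["marker"] < 0.05
    # deterministic trait
    y2 = d.copy()
    spec2 = MixedModelSpec(y=y2, X=np.ones((n, 1)), fixed_names=["int"],
                           random_terms=[RandomTerm("alpha", Z=d)])
    fit2 = fit_variance_components(spec2, method="ML")
    assert variance_explained_by_marker(fit2, y2, ["alpha"])["marker"] > 0.95


def test_liability_multiplier_is_half_pi_at_half_prevalence():
    mult = observed_to_liability_h2(1.0, 0.5)
    assert mult == pytest.approx(np.pi / 2, abs=1e-12)


def test_liability_round_trip_and_edges():
    for h2, k in [(0.3, 0.2), (0.7, 0.9), (0.0, 0.4)]:
        assert liability_to_observed_h2(observed_to_liability_h2(h2, k), k) == pytest.approx(
            h2, abs=1e-12
        )
    assert observed_to_liability_h2(0.0, 0.3) == 0.0
    with pytest.raises(ValueError):
        observed_to_liability_h2(0.5, 0.0)
    with pytest.raises(ValueError):
        observed_to_liability_h2(1.5, 0.5)


def test_rotated_and_dense_paths_agree():
    rng = np.random.default_rng(10)
    n = 80
    K = _random_psd(n, rng)
    g = rng.multivariate_normal(np.zeros(n), 0.5 * K)
    y = g + rng.normal(0, 1, size=n)
    X = np.ones((n, 1))
    # rotated path: single animal-dim K
    f_rot = fit_variance_components(
        MixedModelSpec(y=y, X=X, fixed_names=["int"],
                       random_terms=[RandomTerm("g", Z=None, K=K)]), method="REML")
    # dense path forced by an explicit identity second covariance
    f_dense = fit_variance_components(
        MixedModelSpec(y=y, X=X, fixed_names=["int"],
                       random_terms=[RandomTerm("g", Z=None, K=K),
                                     RandomTerm("g2", Z=None, K=np.eye(n))]),
        method="REML")
    # the identity term is redundant with the residual: total loglik must match
    assert f_dense.loglik_reml == pytest.approx(f_rot.loglik_reml, abs=1e-3)
    assert f_dense.varcomps["g"] == pytest.approx(f_rot.varcomps["g"], rel=0.1, abs=0.05)
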