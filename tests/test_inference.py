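"""Weighted-PLS machinery: thinning, weights, components, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from climdebt import inference as inf


def synthetic_regression(n=400, p=5, betas=None, noise=0.5, seed=0, extent=80_000.0):
    """Standardized predictors with a known linear signal plus coordinates."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    if betas is None:
        betas = np.linspace(1.0, 0.2, p)
    y = X @ np.asarray(betas) + noise * rng.standard_normal(n)
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(p)])
    df["dT"] = y
    df["x"] = rng.uniform(0, extent, n)
    df["y"] = rng.uniform(0, extent, n)
    df["year"] = rng.integers(1993, 2009, n)
    return df, np.asarray(betas)


# -- draw machinery --------------------------------------------------------

def test_spatial_thinning_respects_min_distance(rng):
    x = rng.uniform(0, 50_000, 300)
    y = rng.uniform(0, 50_000, 300)
    idx = inf.spatial_thinning(x, y, min_dist=10_000.0, rng=rng)
    pts = np.column_stack([x[idx], y[idx]])
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 10_000.0
    assert len(idx) >= 1


def test_spatial_thinning_is_maximal(rng):
    # every dropped point must be within min_dist of some kept point
    x = rng.uniform(0, 30_000, 120)
    y = rng.uniform(0, 30_000, 120)
    idx = inf.spatial_thinning(x, y, min_dist=8_000.0, rng=rng)
    kept = np.zeros(len(x), bool)
    kept[idx] = True
    for i in np.flatnonzero(~kept):
        d = np.sqrt((x[idx] - x[i]) ** 2 + (y[idx] - y[i]) ** 2)
        assert d.min() < 8_000.0


def test_observation_weights_even_out_years():
    years = np.array([2000, 2000, 2000, 2001, 2002, 2002])
    w = inf.observation_weights(years)
    assert np.allclose(w, [1 / 3, 1 / 3, 1 / 3, 1.0, 1 / 2, 1 / 2])
    for yr in np.unique(years):
        assert w[years == yr].sum() == pytest.approx(1.0)


def test_standardize_weighted_moments(rng):
    v = rng.normal(3.0, 2.0, 200)
    w = rng.uniform(0.5, 2.0, 200)
    z, mu, sd = inf.standardize(v, w)
    wn = w / w.sum()
    assert wn @ z == pytest.approx(0.0, abs=1e-12)
    assert wn @ z**2 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        inf.standardize(np.full(10, 2.5), np.ones(10))


# -- weighted PLS core -----------------------------------------------------

def standardized_problem(n=150, p=4, seed=3, weighted=True):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = X @ rng.normal(size=p) + 0.3 * rng.standard_normal(n)
    w = rng.uniform(0.2, 1.0, n) if weighted else np.ones(n)
    Xs = np.empty_like(X)
    for j in range(p):
        Xs[:, j], _, _ = inf.standardize(X[:, j], w)
    ys, _, _ = inf.standardize(y, w)
    return Xs, ys, w


def test_scores_are_weighted_orthogonal():
    Xs, ys, w = standardized_problem()
    fit = inf.fit_weighted_pls(Xs, ys, w)
    wn = w / w.sum()
    g = fit.scores.T @ (wn[:, None] * fit.scores)
    off = g - np.diag(np.diag(g))
    assert np.max(np.abs(off)) < 1e-10


def test_rotation_reproduces_scores():
    Xs, ys, w = standardized_problem()
    fit = inf.fit_weighted_pls(Xs, ys, w)
    assert np.allclose(Xs @ fit.rotation, fit.scores, atol=1e-8)


def test_full_component_weighted_pls_equals_weighted_ols():
    Xs, ys, w = standardized_problem(weighted=True)
    fit = inf.fit_weighted_pls(Xs, ys, w)
    coefs, r2 = inf.coefficients_and_r2(fit, np.arange(fit.n_components))
    W = np.diag(w / w.sum())
    ols = np.linalg.solve(Xs.T @ W @ Xs, Xs.T @ W @ ys)
    assert np.allclose(coefs, ols, atol=1e-8)
    assert 0.0 <= r2 <= 1.0


def test_zero_variance_predictor_is_named():
    Xs, ys, w = standardized_problem()
    Xs[:, 2] = 0.0
    with pytest.raises(ValueError, match="c2"):
        inf.fit_weighted_pls(Xs, ys, w, predictor_names=["c0", "c1", "c2", "c3"])


def test_select_components_drops_noise_dimensions():
    rng = np.random.default_rng(9)
    n = 300
    signal = rng.standard_normal(n)
    X = np.column_stack([signal, rng.standard_normal((n, 3))])
    y = signal + 0.2 * rng.standard_normal(n)
    w = np.ones(n)
    Xs = np.empty_like(X)
    for j in range(4):
        Xs[:, j], _, _ = inf.standardize(X[:, j], w)
    ys, _, _ = inf.standardize(y, w)
    fit = inf.fit_weighted_pls(Xs, ys, w)
    retained, pvals = inf.select_components(fit, ys, alpha=0.05)
    assert 0 in retained
    assert len(retained) < fit.n_components
    assert pvals.shape == (fit.n_components,)


def test_variance_partition_sums_to_r2(rng):
    for _ in range(10):
        n, p = 80, 6
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        w = rng.uniform(0.1, 1.0, n)
        Xs = np.empty_like(X)
        for j in range(p):
            Xs[:, j], _, _ = inf.standardize(X[:, j], w)
        ys, _, _ = inf.standardize(y, w)
        fit = inf.fit_weighted_pls(Xs, ys, w)
        k = rng.integers(1, fit.n_components + 1)
        retained = rng.choice(fit.n_components, size=k, replace=False)
        shares = inf.variance_partition(fit, retained)
        _, r2 = inf.coefficients_and_r2(fit, retained)
        assert shares.sum() == pytest.approx(r2, abs=1e-10)
        assert np.all(shares >= -1e-12)


# -- significance and bootstrap -------------------------------------------

def test_sign_test_thresholds():
    pos = np.abs(np.random.default_rng(0).normal(1, 0.1, 500))
    sig, direction, frac = inf.coefficient_significance(pos, alpha=0.01)
    assert sig and direction == "positive" and frac == 1.0
    mixed = np.concatenate([pos, -pos[:50]])
    sig, direction, _ = inf.coefficient_significance(mixed, alpha=0.01)
    assert not sig and direction == "none"
    with pytest.raises(ValueError):
        inf.coefficient_significance(pos[:50])


def test_bootstrap_recovers_planted_coefficients():
    betas = np.array([0.8, -0.5, 0.0])
    df, _ = synthetic_regression(n=500, p=3, betas=betas, noise=0.4, seed=2)
    res = inf.bootstrap_pls(
        df, ["v0", "v1", "v2"], n_draws=150, min_dist=10_000.0, seed=0
    )
    summary = res.summary()
    # standardized truth: beta_j * sd(x) / sd(y)
    sd_y = df["dT"].std()
    expected = betas / sd_y
    got = summary["mean"].to_numpy()
    assert np.allclose(got, expected, atol=0.1)
    assert summary.loc["v0", "significant"] and summary.loc["v0", "direction"] == "positive"
    assert summary.loc["v1", "significant"] and summary.loc["v1", "direction"] == "negative"
    assert not summary.loc["v2", "significant"]
    assert res.n_draws == 150
    assert 0.0 <= res.r2_summary()["mean"] <= 1.0


def test_bootstrap_is_reproducible():
    df, _ = synthetic_regression(n=200, p=3, seed=5)
    a = inf.bootstrap_pls(df, ["v0", "v1", "v2"], n_draws=20, seed=42)
    b = inf.bootstrap_pls(df, ["v0", "v1", "v2"], n_draws=20, seed=42)
    assert np.array_equal(a.coefficients, b.coefficients)
    assert np.array_equal(a.draw_sizes, b.draw_sizes)


def test_bootstrap_missing_columns_raise():
    df, _ = synthetic_regression(n=50, p=2, seed=1)
    with pytest.raises(ValueError, match="v9"):
        inf.bootstrap_pls(df, ["v0", "v9"], n_draws=5)


def test_error_propagation_perturbs_predictors_only():
    df, _ = synthetic_regression(n=300, p=2, betas=[1.0, 0.0], noise=0.2, seed=6)
    # heavy predictor noise makes some draws retain no component, so draw
    # enough that >= 100 succeed (the sign test's minimum)
    clean = inf.bootstrap_pls(df, ["v0", "v1"], n_draws=250, seed=3)
    noisy = inf.error_propagation(
        df, ["v0", "v1"], {"v0": 2.0}, n_draws=250, seed=3
    )
    # heavy measurement error on v0 attenuates its coefficient
    assert abs(noisy.summary().loc["v0", "mean"]) < abs(clean.summary().loc["v0", "mean"])
    with pytest.raises(ValueError):
        inf.error_propagation(df, ["v0", "v1"], {"v0": -1.0}, n_draws=5)


def test_variant_survey_filters():
    df, _ = synthetic_regression(n=200, p=2, seed=7)
    df["SILVP"] = (np.arange(200) % 2).astype(int)
    df["DISTURB"] = 0
    df["EXOT"] = 0
    assert len(inf.select_variant_surveys(df, "PLS0")) == 200
    late = inf.select_variant_surveys(df, "PLS1", late_start=2000)
    assert (late["year"] >= 2000).all()
    pls3 = inf.select_variant_surveys(df, "PLS3", late_start=2000)
    assert (pls3[["SILVP", "DISTURB", "EXOT"]].max(axis=1) > 0).all()
    pls4 = inf.select_variant_surveys(df, "PLS4", late_start=2000)
    assert (pls4[["SILVP", "DISTURB", "EXOT"]].max(axis=1) == 0).all()
    assert len(pls3) + len(pls4) == len(late)
    with pytest.raises(ValueError):
        inf.select_variant_surveys(df, "PLS9")


def test_variant_column_sets():
    assert inf.VARIANT_COLUMNS["PLS0"][-1] == "time"
    assert "TBUF" in inf.VARIANT_COLUMNS["PLS2"]
    assert inf.VARIANT_COLUMNS["PLS2"][-1] == "time"
    assert len(inf.VARIANT_COLUMNS["PLS2"]) == len(inf.VARIANT_COLUMNS["PLS0"]) + 4


def test_single_fit_residuals_units_and_indices():
    df, _ = synthetic_regression(n=250, p=3, seed=8)
    idx, resid = inf.single_fit_residuals(df, ["v0", "v1", "v2"], seed=0)
    assert len(idx) == len(resid)
    assert np.all(idx < len(df))
    assert np.std(resid) < df["dT"].std()  # model explains part of the variance
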