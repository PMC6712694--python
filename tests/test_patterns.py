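"""Association models: PLS/target projection, MLR, ilr-MLR, bivariate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actipattern.patterns import (
    PLSTargetProjection,
    SingularityError,
    bivariate_correlations,
    fit_ilr_mlr,
    fit_mlr,
    monte_carlo_cv,
)


def make_xy(n=120, p=6, seed=0, noise=1.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


# -- PLS core ---------------------------------------------------------------


def test_pls_full_components_equals_ols():
    X, y = make_xy(seed=1)
    m = PLSTargetProjection(n_components=X.shape[1]).fit(X, y)
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    b_ols = np.linalg.solve(Xs.T @ Xs, Xs.T @ ys)  # independent normal equations
    np.testing.assert_allclose(m.coef_, b_ols, atol=1e-8)
    np.testing.assert_allclose(m.predict(X), y.mean() + y.std(ddof=1) * (Xs @ b_ols), atol=1e-8)


def test_pls_univariate_equals_simple_least_squares():
    X, y = make_xy(p=1, seed=2)
    m = PLSTargetProjection(n_components=1).fit(X, y)
    slope = np.cov(X[:, 0], y, ddof=1)[0, 1] / np.var(X[:, 0], ddof=1)
    pred = y.mean() + slope * (X[:, 0] - X[:, 0].mean())
    np.testing.assert_allclose(m.predict(X), pred, atol=1e-10)


def test_pls_matches_sklearn_predictions():
    from sklearn.cross_decomposition import PLSRegression

    X, y = make_xy(n=150, p=8, seed=3)
    for a in (1, 3, 5):
        ours = PLSTargetProjection(n_components=a).fit(X, y)
        theirs = PLSRegression(n_components=a, scale=True).fit(X, y)
        np.testing.assert_allclose(ours.predict(X), theirs.predict(X).ravel(), atol=1e-8)


def test_pls_handles_duplicated_column_symmetrically():
    X, y = make_xy(n=100, p=4, seed=4)
    Xd = np.column_stack([X, X[:, 0]])
    m = PLSTargetProjection(n_components=3).fit(Xd, y)
    assert m.coef_[0] == pytest.approx(m.coef_[-1], abs=1e-12)
    assert m.selectivity_ratio_[0] == pytest.approx(m.selectivity_ratio_[-1], abs=1e-12)


def test_pls_scores_orthogonal(small_dataset):
    m = PLSTargetProjection(n_components=5).fit(
        small_dataset.X(), small_dataset.outcome.to_numpy()
    )
    G = m.x_scores_.T @ m.x_scores_
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.diag(G).max()


# -- target projection & selectivity ratios ---------------------------------


def test_tp_prediction_equivalence():
    X, y = make_xy(n=200, p=10, seed=5, noise=2.0)
    m = PLSTargetProjection(n_components=3).fit(X, y)
    yhat_full = ((X - X.mean(0)) / X.std(0, ddof=1)) @ m.coef_
    yhat_tp = m.tp_scores_ * np.linalg.norm(m.coef_)
    np.testing.assert_allclose(yhat_full, yhat_tp, atol=1e-10)
    assert np.linalg.norm(m.tp_weights_) == pytest.approx(1.0, abs=1e-12)
    assert (m.explained_variance_ <= m.total_variance_ + 1e-12).all()


def test_one_component_tp_equals_the_component():
    X, y = make_xy(n=100, p=5, seed=6)
    m = PLSTargetProjection(n_components=1).fit(X, y)
    t = m.x_scores_[:, 0]
    align = np.sign(t @ m.tp_scores_)
    np.testing.assert_allclose(m.tp_scores_, align * t, atol=1e-10)


def test_tp_weights_orthonormal_limit():
    """With orthonormal columns the TP axis follows covariance with y."""
    rng = np.random.default_rng(7)
    Q, _ = np.linalg.qr(rng.standard_normal((300, 5)))
    X = Q * np.sqrt(300)
    y = X @ np.array([2.0, -1.0, 0.5, 0.0, 0.0]) + 0.1 * rng.standard_normal(300)
    m = PLSTargetProjection(n_components=5).fit(X, y)
    cov = ((X - X.mean(0)) / X.std(0, ddof=1) * ((y - y.mean()))[:, None]).mean(0)
    w = cov / np.linalg.norm(cov)
    # direction agreement up to the residual noise scale
    assert abs(m.tp_weights_ @ w) > 0.999


def test_sr_is_one_for_noise_free_copy_of_y():
    """When the model reproduces y exactly, the copy's variance is fully
    explained by the target-projected component."""
    rng = np.random.default_rng(8)
    y = rng.standard_normal(200)
    X = np.column_stack([y, rng.standard_normal((200, 3))])
    m = PLSTargetProjection(n_components=4).fit(X, y)
    assert m.fitted_r2_ == pytest.approx(1.0, abs=1e-10)
    assert abs(m.selectivity_ratio_[0]) == pytest.approx(1.0, abs=1e-6)


def test_sr_vanishes_for_independent_variable():
    rng = np.random.default_rng(9)
    n = 5000
    X = rng.standard_normal((n, 4))
    y = X[:, 1] + 0.5 * rng.standard_normal(n)
    m = PLSTargetProjection(n_components=2).fit(X, y)
    assert abs(m.selectivity_ratio_[0]) < 0.01


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_sr_bounded_by_one_property(seed):
    rng = np.random.default_rng(seed)
    n, p = 40, rng.integers(2, 8)
    X = rng.standard_normal((n, p)) * rng.uniform(0.5, 3, p)
    y = rng.standard_normal(n)
    m = PLSTargetProjection(n_components=min(3, p)).fit(X, y)
    assert (np.abs(m.selectivity_ratio_) <= 1 + 1e-10).all()


def test_sr_cis_deterministic_and_contain_estimate(small_dataset):
    X, y = small_dataset.X(), small_dataset.outcome.to_numpy()
    kw = dict(n_components=2, ci_reps=100, random_state=5)
    a = PLSTargetProjection(**kw).fit(X, y)
    b = PLSTargetProjection(**kw).fit(X, y)
    np.testing.assert_array_equal(a.sr_ci_.to_numpy(), b.sr_ci_.to_numpy())
    pat = a.association_pattern()
    assert (pat.table["ci_low"] <= pat.table["estimate"] + 1e-12).all()
    assert (pat.table["estimate"] <= pat.table["ci_high"] + 1e-12).all()


def test_noise_free_single_effect_ci_width_shrinks():
    from actipattern.simulate import SyntheticConfig, generate_spectrum_dataset

    eff = np.zeros(23)
    eff[20] = -1.0
    widths = []
    for n in (100, 800):
        d = generate_spectrum_dataset(
            SyntheticConfig(
                n_participants=n, latent_loading=0.0, ar_rho=0.0,
                effect_vector=eff, noise_sd=0.0, seed=12,
            )
        )
        m = PLSTargetProjection(n_components=1, ci_reps=60, random_state=3).fit(
            d.X(), d.outcome.to_numpy()
        )
        widths.append(float(m.sr_ci_["ci_high"].iloc[20] - m.sr_ci_["ci_low"].iloc[20]))
    assert widths[1] < widths[0]


# -- Monte Carlo cross-validation -------------------------------------------


def test_mc_cv_deterministic():
    X, y = make_xy(n=80, p=5, seed=10)
    a = monte_carlo_cv(X, y, reps=50, seed=3)
    b = monte_carlo_cv(X, y, reps=50, seed=3)
    np.testing.assert_array_equal(a["rmsep_mean"], b["rmsep_mean"])
    assert a["n_components"] == b["n_components"]


def test_mc_cv_pure_noise_selects_one_component_with_no_skill():
    rng = np.random.default_rng(11)
    X = rng.standard_normal((120, 6))
    y = rng.standard_normal(120)
    sel = monte_carlo_cv(X, y, reps=200, seed=4)
    assert sel["n_components"] == 1
    assert sel["q2"] <= 0.05


def test_mc_cv_recovers_two_latent_directions():
    """Two orthogonal signal directions at low noise need >= 2 components."""
    hits = 0
    for seed in range(50):
        rng = np.random.default_rng(seed)
        n, p = 150, 10
        basis, _ = np.linalg.qr(rng.standard_normal((p, 2)))
        scores = rng.standard_normal((n, 2))
        X = scores @ basis.T + 0.05 * rng.standard_normal((n, p))
        y = scores[:, 0] + scores[:, 1] + 0.05 * rng.standard_normal(n)
        sel = monte_carlo_cv(X, y, max_components=5, reps=60, seed=seed + 1)
        hits += sel["n_components"] >= 2
    assert hits >= 48  # >= 95% of seeds


def test_mc_cv_input_validation():
    X, y = make_xy(n=30, p=3, seed=12)
    with pytest.raises(ValueError):
        monte_carlo_cv(X, y, reps=1)
    with pytest.raises(ValueError):
        monte_carlo_cv(X[:10], y[:10], reps=10)


# -- multiple linear regression ---------------------------------------------


def test_mlr_noise_free_recovers_coefficients():
    rng = np.random.default_rng(13)
    X = rng.standard_normal((50, 3))
    y = 2.0 * X[:, 0]
    pat = fit_mlr(X, y)
    assert pat.estimates[0] == pytest.approx(2.0, abs=1e-10)
    np.testing.assert_allclose(pat.estimates[1:], 0.0, atol=1e-10)


def test_mlr_matches_normal_equations(small_dataset):
    X, y = small_dataset.X(), small_dataset.outcome.to_numpy()
    pat = fit_mlr(X, y)
    D = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    np.testing.assert_allclose(pat.estimates, beta[1:], atol=1e-8)
    assert (pat.table["ci_low"] <= pat.table["estimate"]).all()
    assert (pat.table["estimate"] <= pat.table["ci_high"]).all()


def test_mlr_closed_data_raises_singularity():
    from actipattern.coda import close

    rng = np.random.default_rng(14)
    X = close(rng.uniform(1, 10, size=(60, 5)))
    with pytest.raises(SingularityError, match="closed"):
        fit_mlr(X, rng.standard_normal(60))


def test_mlr_needs_enough_observations():
    X, y = make_xy(n=5, p=6, seed=15)
    with pytest.raises(ValueError):
        fit_mlr(X, y)


# -- ilr MLR ----------------------------------------------------------------


@pytest.mark.parametrize("p,expected_fits", [(4, 4), (23, 23)])
def test_ilr_mlr_one_fit_per_permutation(p, expected_fits, small_dataset):
    X = small_dataset.X()[:, :p] + 1e-6
    y = small_dataset.outcome.to_numpy()
    pat = fit_ilr_mlr(X, y)
    assert pat.meta["n_fits"] == expected_fits
    assert len(pat.table) == expected_fits


def test_ilr_mlr_permutations_share_fitted_values(small_dataset):
    """Every permutation spans the same subspace: identical predictions."""
    import statsmodels.api as sm

    from actipattern.coda import all_first_permutations, close, ilr_pivot

    X = small_dataset.X()[:, :6]
    y = small_dataset.outcome.to_numpy()
    closed = close(X)
    fitted = []
    for perm in all_first_permutations(6):
        Z = sm.add_constant(ilr_pivot(closed, perm))
        fitted.append(sm.OLS(y, Z).fit().fittedvalues)
    for f in fitted[1:]:
        np.testing.assert_allclose(f, fitted[0], atol=1e-8)


# -- bivariate ---------------------------------------------------------------


def test_bivariate_perfect_and_symmetric():
    rng = np.random.default_rng(16)
    y = rng.standard_normal(50)
    X = np.column_stack([y, rng.standard_normal(50)])
    pat = bivariate_correlations(X, y)
    assert pat.estimates[0] == pytest.approx(1.0, abs=1e-12)
    # symmetry r(x, y) == r(y, x)
    r_xy = bivariate_correlations(y[:, None], X[:, 1]).estimates[0]
    assert pat.estimates[1] == pytest.approx(r_xy, abs=1e-12)
    assert (pat.table["ci_low"] <= pat.table["estimate"]).all()


def test_bivariate_null_ci_calibration():
    """Fisher-z intervals cover a true zero roughly 95% of the time."""
    rng = np.random.default_rng(17)
    cover = 0
    runs = 400
    for _ in range(runs):
        x = rng.standard_normal((60, 1))
        y = rng.standard_normal(60)
        pat = bivariate_correlations(x, y)
        cover += pat.table["ci_low"].iloc[0] <= 0 <= pat.table["ci_high"].iloc[0]
    assert 0.91 <= cover / runs <= 0.99


def test_bivariate_flags_constant_column():
    X = np.column_stack([np.ones(30), np.arange(30.0)])
    with pytest.warns(UserWarning, match="constant"):
        pat = bivariate_correlations(X, np.arange(30.0) ** 1.5)
    assert np.isnan(pat.estimates[0])
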