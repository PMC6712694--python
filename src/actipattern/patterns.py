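"""Association models relating an intensity spectrum to a health outcome.

Five routes onto the same question — which parts of the physical-activity
intensity spectrum move with cardiometabolic risk — that differ in how they
cope with the spectrum's multicollinearity:

* bivariate Pearson correlations per bin (ignore the other bins);
* multiple linear regression on the raw minutes (requires a well-conditioned
  design; fails by construction on closed data);
* multiple linear regression on pivot-coordinate ilr data, refit once per
  permutation so every bin takes the interpretable first coordinate;
* multivariate pattern analysis: PLS regression (NIPALS), Monte Carlo
  cross-validated choice of component count, compression of the predictive
  variance onto a single target-projected component, and per-bin selectivity
  ratios (explained / total variance, signed by the target-projection
  loading) with resampled 95% confidence intervals — on raw or clr data.

All modelling is done on centred, unit-variance variables; PLS is fully
deterministic given the data and the resampling seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .coda import all_first_permutations, close, ilr_pivot

CONDITION_NUMBER_LIMIT = 1e10


class SingularityError(np.linalg.LinAlgError):
    """Design matrix is (near-)singular; least squares is undefined."""


@dataclass
class AssociationPattern:
    """Per-bin effect estimates with 95% CIs — the common model output."""

    model_tag: str
    table: pd.DataFrame  # columns: bin, estimate, ci_low, ci_high
    model_r2: float = float("nan")
    cv_q2: float = float("nan")
    meta: dict = field(default_factory=dict)

    @property
    def estimates(self) -> np.ndarray:
        return self.table["estimate"].to_numpy()


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if len(y) != X.shape[0]:
        raise ValueError("X and y lengths differ")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    return X, y


def bivariate_correlations(X, y, names=None) -> AssociationPattern:
    """Per-bin Pearson r with Fisher-z 95% confidence intervals."""
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher-z interval")
    names = list(names) if names is not None else [f"bin_{j}" for j in range(p)]
    sd = X.std(axis=0)
    r = np.full(p, np.nan)
    ok = sd > 0
    if y.std() == 0:
        raise ValueError("outcome is constant")
    Xc = X[:, ok] - X[:, ok].mean(axis=0)
    yc = y - y.mean()
    r[ok] = (Xc * yc[:, None]).sum(axis=0) / (
        np.sqrt((Xc**2).sum(axis=0) * (yc**2).sum())
    )
    if not ok.all():
        warnings.warn(
            f"constant column(s) {[names[j] for j in np.where(~ok)[0]]}: r undefined",
            UserWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
    table = pd.DataFrame(
        {
            "bin": names,
            "estimate": r,
            "ci_low": np.tanh(z - half),
            "ci_high": np.tanh(z + half),
        }
    )
    return AssociationPattern(model_tag="bivariate", table=table, meta={"n": n})


def fit_mlr(X, y, names=None, add_intercept: bool = True) -> AssociationPattern:
    """Ordinary least squares with t-based 95% CIs per coefficient.

    Raises :class:`SingularityError` when the design's condition number
    exceeds 1e10 — as happens, by construction, when the explanatory
    variables are closed (sum to a constant) and an intercept is present.
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    names = list(names) if names is not None else [f"bin_{j}" for j in range(p)]
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    cond = np.linalg.cond(design / np.linalg.norm(design, axis=0))
    if cond > CONDITION_NUMBER_LIMIT:
        raise SingularityError(
            "explanatory variables are singular or near-singular "
            f"(condition number {cond:.3g} > {CONDITION_NUMBER_LIMIT:.0e}); closed "
            "(constant-sum) data with an intercept always triggers this"
        )
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=0.05)
    k0 = 1 if add_intercept else 0
    table = pd.DataFrame(
        {
            "bin": names,
            "estimate": res.params[k0:],
            "ci_low": ci[k0:, 0],
            "ci_high": ci[k0:, 1],
        }
    )
    return AssociationPattern(
        model_tag="mlr_raw",
        table=table,
        model_r2=float(res.rsquared),
        meta={"n": n, "condition_number": float(cond)},
    )


def fit_ilr_mlr(minutes, y, names=None, delta=None) -> AssociationPattern:
    """Compositional MLR via pivot coordinates, one fit per permutation.

    The minutes are closed and ilr-transformed D times, each permutation
    placing a different bin in the first pivot coordinate; the reported
    effect for a bin is the first-coordinate coefficient (and CI) of the fit
    in which that bin leads.  All D fits span the same column space, so their
    fitted values and R^2 coincide.
    """
    X, y = _check_xy(minutes, y)
    n, d = X.shape
    names = list(names) if names is not None else [f"bin_{j}" for j in range(d)]
    closed = close(X, delta=delta)
    est = np.empty(d)
    lo = np.empty(d)
    hi = np.empty(d)
    r2 = np.nan
    for k, perm in enumerate(all_first_permutations(d)):
        Z = ilr_pivot(closed, perm)
        design = sm.add_constant(Z, has_constant="add")
        cond = np.linalg.cond(design / np.linalg.norm(design, axis=0))
        if cond > CONDITION_NUMBER_LIMIT:
            raise SingularityError(
                f"ilr design for permutation {k} is near-singular (cond {cond:.3g})"
            )
        res = sm.OLS(y, design).fit()
        ci = res.conf_int(alpha=0.05)
        est[k], lo[k], hi[k] = res.params[1], ci[1, 0], ci[1, 1]
        r2 = float(res.rsquared)
    table = pd.DataFrame({"bin": names, "estimate": est, "ci_low": lo, "ci_high": hi})
    return AssociationPattern(
        model_tag="mlr_ilr", table=table, model_r2=r2, meta={"n": n, "n_fits": d}
    )


# ---------------------------------------------------------------------------
# PLS / multivariate pattern analysis
# ---------------------------------------------------------------------------


def _nipals(X: np.ndarray, y: np.ndarray, n_components: int, tol: float = 1e-12):
    """NIPALS PLS1 on pre-scaled data; deterministic, tolerates rank deficiency.

    Returns weights W, x-loadings P, y-loadings q (per component) and scores
    T.  Stops early when the residual carries no covariance with y.
    """
    n, p = X.shape
    Xr = X.copy()
    yr = y.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    a_used = 0
    for a in range(n_components):
        w = Xr.T @ yr
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = Xr @ w
        tt = t @ t
        if tt < tol:
            break
        p_a = Xr.T @ t / tt
        q_a = (yr @ t) / tt
        Xr -= np.outer(t, p_a)
        yr = yr - q_a * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t
        a_used += 1
    return W[:, :a_used], P[:, :a_used], Q[:a_used], T[:, :a_used]


def _coef_path(W: np.ndarray, P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Regression vectors (scaled space) for every component count 1..A.

    ``B = W (P'W)^{-1} diag-free Q`` accumulated column-by-column; column
    ``a-1`` of the result is the coefficient vector using ``a`` components.
    """
    a_used = W.shape[1]
    if a_used == 0:
        return np.zeros((W.shape[0], 1))
    R = W @ np.linalg.inv(np.triu(P.T @ W))
    return np.cumsum(R * Q[None, :], axis=1)


class PLSTargetProjection(BaseEstimator, RegressorMixin):
    """PLS1 regression with target projection and selectivity ratios.

    The estimator standardizes all variables, fits PLS components by NIPALS
    (orthogonal scores, covariance-maximizing weights), optionally chooses
    the number of components by Monte Carlo cross-validation (repeated random
    50/50 splits, one-standard-error parsimony rule on held-out RMSEP), then
    compresses the model's entire predictive variance onto one component
    along the regression vector (target projection).  The selectivity ratio
    of a variable is the share of its variance explained by that single
    component, signed by its target-projection loading — a stable, bounded
    ([-1, 1]) summary of each bin's role in the multivariate association
    pattern.  Percentile confidence intervals for the ratios come from the
    same Monte Carlo half-sample machinery.

    Parameters
    ----------
    n_components : int or "auto"
        Fixed component count, or "auto" to select by Monte Carlo CV.
    max_components : int
        Largest count considered under "auto".
    cv_reps : int
        Monte Carlo repetitions for component selection.
    holdout : float
        Fraction held out per repetition (0.5 = half-sample validation).
    ci_reps : int
        Resampling repetitions for selectivity-ratio CIs (0 disables).
    random_state : int or None
        Seed for every resampling step; fixed seed means identical results.

    Attributes (after ``fit``)
    --------------------------
    n_components_, coef_ (scaled space), x_weights_, x_loadings_, x_scores_,
    y_loadings_, fitted_r2_, cv_q2_, rmsep_curve_, tp_weights_, tp_scores_,
    tp_loadings_, explained_variance_, total_variance_, selectivity_ratio_,
    sr_ci_ (DataFrame when ``ci_reps > 0``).
    """

    def __init__(
        self,
        n_components="auto",
        max_components: int = 10,
        cv_reps: int = 1000,
        holdout: float = 0.5,
        ci_reps: int = 0,
        random_state=None,
    ):
        self.n_components = n_components
        self.max_components = max_components
        self.cv_reps = cv_reps
        self.holdout = holdout
        self.ci_reps = ci_reps
        self.random_state = random_state

    # -- scaling helpers ----------------------------------------------------
    @staticmethod
    def _scale_fit(X, y):
        mx, sx = X.mean(axis=0), X.std(axis=0, ddof=1)
        if np.any(sx == 0):
            raise ValueError("constant explanatory column: cannot standardize")
        my, sy = y.mean(), y.std(ddof=1)
        if sy == 0:
            raise ValueError("constant outcome")
        return mx, sx, my, sy

    def fit(self, X, y):
        X, y = _check_xy(X, y)
        n, p = X.shape
        if n < 10:
            raise ValueError("need at least 10 observations")
        rng = np.random.default_rng(self.random_state)
        a_max = int(min(self.max_components, p, n - 1))
        if self.n_components == "auto":
            sel = monte_carlo_cv(
                X,
                y,
                max_components=a_max,
                reps=self.cv_reps,
                holdout=self.holdout,
                rng=rng,
            )
            self.n_components_ = sel["n_components"]
            self.rmsep_curve_ = sel["rmsep_mean"]
            self.cv_q2_ = sel["q2"]
        else:
            a = int(self.n_components)
            if not 1 <= a <= min(n - 1, p):
                raise ValueError(f"n_components={a} out of range for n={n}, p={p}")
            self.n_components_ = a
            self.rmsep_curve_ = None
            self.cv_q2_ = float("nan")
        self._mx, self._sx, self._my, self._sy = self._scale_fit(X, y)
        Xs = (X - self._mx) / self._sx
        ys = (y - self._my) / self._sy
        W, P, Q, T = _nipals(Xs, ys, self.n_components_)
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, Q, T
        self.n_components_ = W.shape[1] if W.shape[1] else 1
        self.coef_ = _coef_path(W, P, Q)[:, -1]
        yhat = Xs @ self.coef_
        self.fitted_r2_ = float(1.0 - ((ys - yhat) ** 2).sum() / (ys**2).sum())
        self._target_projection(Xs)
        if self.ci_reps:
            self.sr_ci_ = self._sr_confidence_intervals(X, y, rng)
        self.n_features_in_ = p
        return self

    def _target_projection(self, Xs: np.ndarray):
        b = self.coef_
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError("zero regression vector: degenerate model")
        n = Xs.shape[0]
        w = b / nb
        t = Xs @ w
        tt = t @ t
        p_tp = Xs.T @ t / tt
        self.tp_weights_ = w
        self.tp_scores_ = t
        self.tp_loadings_ = p_tp
        self.explained_variance_ = (p_tp**2) * tt / (n - 1)
        self.total_variance_ = (Xs**2).sum(axis=0) / (n - 1)
        self.selectivity_ratio_ = np.sign(p_tp) * self.explained_variance_ / self.total_variance_

    @staticmethod
    def _sr_from_scaled(Xs: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Signed selectivity ratios and the TP axis for one fitted half."""
        nb = np.linalg.norm(b)
        if nb == 0:
            return np.zeros(Xs.shape[1]), np.zeros(Xs.shape[1])
        w = b / nb
        t = Xs @ w
        tt = t @ t
        p_tp = Xs.T @ t / tt
        explained = (p_tp**2) * tt
        total = (Xs**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sr = np.sign(p_tp) * explained / total
        return sr, w

    def _sr_confidence_intervals(self, X, y, rng) -> pd.DataFrame:
        n, p = X.shape
        n_train = n - int(round(n * self.holdout))
        srs = np.empty((self.ci_reps, p))
        for r in range(self.ci_reps):
            idx = rng.permutation(n)[:n_train]
            Xt, yt = X[idx], y[idx]
            mx, sx = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
            sx[sx == 0] = 1.0
            my, sy = yt.mean(), yt.std(ddof=1)
            Xs = (Xt - mx) / sx
            ys = (yt - my) / (sy if sy else 1.0)
            W, P, Q, _ = _nipals(Xs, ys, self.n_components_)
            b = _coef_path(W, P, Q)[:, -1]
            sr, w = self._sr_from_scaled(Xs, b)
            if w @ self.tp_weights_ < 0:  # sign-align the TP axis to the full fit
                sr = -sr
            srs[r] = sr
        lo, hi = np.nanpercentile(srs, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "estimate": self.selectivity_ratio_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return self._my + self._sy * (((X - self._mx) / self._sx) @ self.coef_)

    def association_pattern(self, names=None, tag="mpa_raw") -> AssociationPattern:
        """Selectivity-ratio pattern with CIs as an :class:`AssociationPattern`."""
        check_is_fitted(self, "selectivity_ratio_")
        p = len(self.selectivity_ratio_)
        names = list(names) if names is not None else [f"bin_{j}" for j in range(p)]
        if hasattr(self, "sr_ci_"):
            lo, hi = self.sr_ci_["ci_low"].to_numpy(), self.sr_ci_["ci_high"].to_numpy()
            # the full-data point estimate can sit just outside the percentile
            # band; widen to contain it so the pattern is self-consistent
            lo = np.minimum(lo, self.selectivity_ratio_)
            hi = np.maximum(hi, self.selectivity_ratio_)
        else:
            lo = hi = np.full(p, np.nan)
        table = pd.DataFrame(
            {
                "bin": names,
                "estimate": self.selectivity_ratio_,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
        return AssociationPattern(
            model_tag=tag,
            table=table,
            model_r2=self.fitted_r2_,
            cv_q2=self.cv_q2_,
            meta={"n_components": self.n_components_},
        )


def monte_carlo_cv(
    X,
    y,
    max_components: int = 10,
    reps: int = 1000,
    holdout: float = 0.5,
    seed=None,
    rng=None,
) -> dict:
    """Choose the PLS component count by repeated random half-validation.

    For each repetition a random ``holdout`` fraction is set aside, PLS is
    fit on the remainder for 1..max_components components, and held-out RMSEP
    is recorded.  The chosen count is the smallest whose mean RMSEP lies
    within one standard error of the minimum.  Q^2 is the pooled held-out
    ``1 - PRESS/TSS`` at the chosen count (TSS about the training mean).
    """
    X, y = _check_xy(X, y)
    n, p = X.shape
    if n < 20:
        raise ValueError("need n >= 20 for Monte Carlo validation")
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    if not 0 < holdout < 1:
        raise ValueError("holdout must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    a_max = int(min(max_components, p, n - int(round(n * holdout)) - 1))
    n_val = int(round(n * holdout))
    sq_err = np.empty((reps, a_max))
    press = np.empty(reps)
    tss = np.empty(reps)
    for r in range(reps):
        idx = rng.permutation(n)
        val, train = idx[:n_val], idx[n_val:]
        Xt, yt = X[train], y[train]
        mx, sx = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
        sx[sx == 0] = 1.0
        my, sy = yt.mean(), yt.std(ddof=1)
        if sy == 0:
            sy = 1.0
        W, P, Q, _ = _nipals((Xt - mx) / sx, (yt - my) / sy, a_max)
        B = _coef_path(W, P, Q)
        if B.shape[1] < a_max:  # rank ran out: keep the last usable model
            B = np.column_stack([B] + [B[:, -1:]] * (a_max - B.shape[1]))
        preds = my + sy * (((X[val] - mx) / sx) @ B)
        resid = y[val][:, None] - preds
        sq_err[r] = (resid**2).mean(axis=0)
        tss[r] = ((y[val] - my) ** 2).sum()
    rmsep = np.sqrt(sq_err)
    mean = rmsep.mean(axis=0)
    se = rmsep.std(axis=0, ddof=1) / np.sqrt(reps)
    best = int(np.argmin(mean))
    a_star = int(np.argmax(mean <= mean[best] + se[best])) + 1
    press = sq_err[:, a_star - 1] * n_val
    q2 = float(1.0 - press.sum() / tss.sum())
    return {
        "n_components": a_star,
        "rmsep_mean": mean,
        "rmsep_se": se,
        "q2": q2,
        "reps": reps,
    }


def fit_pls(X, y, n_components: int) -> PLSTargetProjection:
    """Fit a fixed-size PLS model (no cross-validation, no CIs)."""
    return PLSTargetProjection(n_components=n_components).fit(X, y)


def fit_mpa(
    X,
    y,
    names=None,
    tag: str = "mpa_raw",
    reps: int = 1000,
    holdout: float = 0.5,
    max_components: int = 10,
    seed=None,
) -> tuple[AssociationPattern, PLSTargetProjection]:
    """Full multivariate pattern analysis: CV, target projection, SR + CIs."""
    model = PLSTargetProjection(
        n_components="auto",
        max_components=max_components,
        cv_reps=reps,
        holdout=holdout,
        ci_reps=reps,
        random_state=seed,
    ).fit(X, y)
    return model.association_pattern(names=names, tag=tag), model
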