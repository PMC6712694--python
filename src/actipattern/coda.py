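"""Compositional machinery: closure, clr, pivot-coordinate ilr, closure diagnostics.

Time-use variables are *closed*: per participant, minutes across intensity bins
sum to that participant's wear time. Normalising to proportions therefore puts
the data on the simplex, where ordinary covariance analysis is distorted (the
off-diagonal correlation mass of a closed matrix sums to -1). The standard
remedies are log-ratio coordinates:

* clr (centred log-ratio): ``ln(x_j) - mean_k ln(x_k)``; symmetric, but the
  coordinates sum to zero per observation, so the design stays singular.
* ilr pivot coordinates: ``z_i = sqrt((D-i)/(D-i+1)) * ln(x_i / g(x_{i+1..D}))``
  for ``i = 1..D-1`` where ``g`` is the geometric mean of the remaining parts.
  The first coordinate isolates one part against the rest; re-running the
  transform once with every part pivoted to the front yields an interpretable
  coefficient for each part.

Both transforms are scale invariant, so minutes/day and proportions of wear
time give identical coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


class CompositionError(ValueError):
    """Raised for vectors that cannot form a valid composition."""


def _as_2d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise CompositionError(f"expected 1-d or 2-d input, got ndim={a.ndim}")
    return a


def multiplicative_zero_replacement(
    x: np.ndarray, delta: float | np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Replace zeros with a small positive amount, shrinking positive parts.

    Rows must be non-negative with at least one positive entry.  ``delta`` may
    be a scalar or per-column vector; by default it is
    ``min(1/60, 0.65 * smallest nonzero value in that column)`` on the raw
    scale — one accelerometer second, or well below the smallest observed
    occupancy, whichever is smaller.  Returns the repaired matrix and a log of
    what was replaced.
    """
    x = _as_2d(x)
    if np.any(x < 0):
        raise CompositionError("negative entries cannot form a composition")
    row_tot = x.sum(axis=1)
    if np.any(row_tot <= 0):
        raise CompositionError("all-zero row: composition undefined")
    zeros = x == 0
    if not zeros.any():
        return x.copy(), {"n_zeros": 0, "delta": None}
    if delta is None:
        col_min = np.where(x > 0, x, np.inf).min(axis=0)
        delta = np.minimum(1.0 / 60.0, 0.65 * col_min)
        delta = np.where(np.isfinite(delta), delta, 1.0 / 60.0)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (x.shape[1],))
    out = x.astype(float).copy()
    add = zeros * delta[None, :]
    added = add.sum(axis=1)
    # shrink the positive parts so the row total is preserved
    shrink = (row_tot - added) / row_tot
    out = np.where(zeros, add, out * shrink[:, None])
    if np.any(shrink <= 0):
        raise CompositionError("zero-replacement delta exceeds the row total")
    return out, {
        "n_zeros": int(zeros.sum()),
        "delta": np.asarray(delta).tolist(),
        "rows_touched": np.where(zeros.any(axis=1))[0].tolist(),
    }


def close(minutes, delta: float | np.ndarray | None = None) -> np.ndarray:
    """Close non-negative vectors to proportions summing to 1.

    Zeros are first repaired by :func:`multiplicative_zero_replacement` so the
    result supports log-ratio transforms.  Accepts a single vector or a matrix
    of row vectors; returns the same shape.
    """
    x = np.asarray(minutes, dtype=float)
    squeeze = x.ndim == 1
    repaired, _ = multiplicative_zero_replacement(_as_2d(x), delta=delta)
    closed = repaired / repaired.sum(axis=1, keepdims=True)
    return closed[0] if squeeze else closed


def clr(composition) -> np.ndarray:
    """Centred log-ratio: log parts relative to their geometric mean.

    Coordinates sum to zero per observation; the transform does not remove
    the singularity of closed data.
    """
    x = np.asarray(composition, dtype=float)
    squeeze = x.ndim == 1
    x2 = _as_2d(x)
    if np.any(x2 <= 0):
        raise CompositionError("clr requires strictly positive parts (close() first)")
    lx = np.log(x2)
    out = lx - lx.mean(axis=1, keepdims=True)
    return out[0] if squeeze else out


def ilr_pivot(composition, permutation=None) -> np.ndarray:
    """Pivot-coordinate ilr with part ``permutation[0]`` isolated first.

    After reordering parts by ``permutation``, coordinate ``i`` (1-based)
    contrasts part ``i`` against the geometric mean of all later parts:
    ``z_i = sqrt((D-i)/(D-i+1)) * ln(x_i / g(x_{i+1..D}))``.
    Returns D-1 coordinates; their squared norm equals the squared norm of the
    clr coordinates of the same composition (isometry).
    """
    x = np.asarray(composition, dtype=float)
    squeeze = x.ndim == 1
    x2 = _as_2d(x)
    if np.any(x2 <= 0):
        raise CompositionError("ilr requires strictly positive parts (close() first)")
    d = x2.shape[1]
    if d < 2:
        raise CompositionError("ilr needs at least 2 parts")
    if permutation is None:
        permutation = np.arange(d)
    perm = np.asarray(permutation, dtype=int)
    if sorted(perm.tolist()) != list(range(d)):
        raise CompositionError(f"permutation must be a bijection on 0..{d - 1}")
    lx = np.log(x2[:, perm])
    # suffix mean of logs: mean over parts i+1..D for each pivot i
    rev_cum = np.cumsum(lx[:, ::-1], axis=1)[:, ::-1]
    i = np.arange(1, d)  # 1-based pivot index, 1..D-1
    tail_mean = (rev_cum[:, 1:]) / (d - i)[None, :]
    coef = np.sqrt((d - i) / (d - i + 1.0))
    z = coef[None, :] * (lx[:, :-1] - tail_mean)
    return z[0] if squeeze else z


def all_first_permutations(d: int) -> list[np.ndarray]:
    """The D cyclic permutations placing each part first exactly once."""
    if d < 2:
        raise CompositionError("need at least 2 parts to permute")
    return [np.roll(np.arange(d), -k) for k in range(d)]


class CLRTransform(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: close rows then apply clr.

    Parameters
    ----------
    delta : float or array, optional
        Zero-replacement amount passed to :func:`close`.
    """

    def __init__(self, delta=None):
        self.delta = delta

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return clr(close(_as_2d(X), delta=self.delta))

    def get_feature_names_out(self, input_features=None):
        if input_features is None:
            input_features = [f"bin_{j}" for j in range(self.n_features_in_)]
        return np.asarray([f"clr_{name}" for name in input_features])


class ILRPivot(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: close rows then pivot-coordinate ilr.

    ``pivot`` selects which part is isolated by the first coordinate; the
    remaining parts follow in the original cyclic order.
    """

    def __init__(self, pivot: int = 0, delta=None):
        self.pivot = pivot
        self.delta = delta

    def fit(self, X, y=None):
        X = _as_2d(X)
        self.n_features_in_ = X.shape[1]
        if not 0 <= self.pivot < self.n_features_in_:
            raise CompositionError(f"pivot {self.pivot} out of range")
        self.permutation_ = np.roll(np.arange(self.n_features_in_), -self.pivot)
        return self

    def transform(self, X):
        return ilr_pivot(close(_as_2d(X), delta=self.delta), self.permutation_)


@dataclass
class ClosureReport:
    """Paired correlation structure of a raw matrix and its transform."""

    corr_raw: pd.DataFrame
    corr_transformed: pd.DataFrame
    difference: pd.DataFrame
    mean_abs_change: float
    n_sign_flips: int
    undefined_columns: list = field(default_factory=list)


def closure_correlation_report(raw, transformed, names=None) -> ClosureReport:
    """Pearson correlation matrices of raw and transformed data and their drift.

    Summarises how much a transform (closure, clr, ...) distorts the pairwise
    correlation structure: mean absolute change and the number of off-diagonal
    sign flips.  Constant columns yield undefined correlations and are flagged.
    """
    raw = _as_2d(raw)
    transformed = _as_2d(transformed)
    if raw.shape != transformed.shape:
        raise ValueError("raw and transformed matrices must share dimensions")
    if names is None:
        names = [f"bin_{j}" for j in range(raw.shape[1])]
    undefined = []
    for tag, mat in (("raw", raw), ("transformed", transformed)):
        sd = mat.std(axis=0)
        undefined += [(tag, names[j]) for j in np.where(sd == 0)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        cr = np.corrcoef(raw, rowvar=False)
        ct = np.corrcoef(transformed, rowvar=False)
    diff = ct - cr
    off = ~np.eye(raw.shape[1], dtype=bool)
    finite = off & np.isfinite(diff)
    flips = finite & (np.sign(cr) != np.sign(ct)) & (cr != 0) & (ct != 0)
    return ClosureReport(
        corr_raw=pd.DataFrame(cr, index=names, columns=names),
        corr_transformed=pd.DataFrame(ct, index=names, columns=names),
        difference=pd.DataFrame(diff, index=names, columns=names),
        mean_abs_change=float(np.abs(diff[finite]).mean()) if finite.any() else 0.0,
        n_sign_flips=int(flips.sum() // 2),
        undefined_columns=undefined,
    )
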