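"""Cardiometabolic indicators and the composite risk score used as outcome.

The composite score is the mean of six sex- and age-adjusted z-scores:
systolic blood pressure, triglycerides, total:HDL cholesterol ratio, HOMA
insulin resistance, waist:height ratio, and the Andersen intermittent
shuttle-run distance with its sign reversed (fitness is protective).  A higher
score means higher cardiometabolic risk; by construction the score has sample
mean 0.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: columns a participant panel must provide
PANEL_COLUMNS = [
    "id",
    "sex",
    "age",
    "waist",
    "height",
    "sbp",
    "tg",
    "tc",
    "hdl",
    "glucose",
    "insulin",
    "andersen",
]

#: the six standardized components averaged into the composite
COMPOSITE_COMPONENTS = ["sbp", "tg", "tc_hdl", "homa", "waist_height", "andersen"]

#: conversion factor between insulin mU/L and pmol/L
MU_PER_PMOL = 6.945


class FriedewaldValidityWarning(UserWarning):
    """Triglycerides at or above 4.5 mmol/L: the LDL estimate is unreliable."""


def homa(glucose, insulin, insulin_units: str = "pmol"):
    """Homeostasis-model insulin-resistance index: ``glucose * insulin / 22.5``.

    Glucose is in mmol/L.  With ``insulin_units="pmol"`` the insulin value is
    used exactly as supplied (pmol/L against the 22.5 constant, as the index
    is sometimes printed).  With ``insulin_units="mU"`` a pmol/L insulin input
    is first converted to mU/L (divided by 6.945), recovering the classic
    form of the index; cohort tables are not always explicit about which scale
    they used, so both are provided.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose <= 0) or np.any(insulin <= 0):
        raise ValueError("glucose and insulin must be positive")
    if insulin_units == "mU":
        insulin = insulin / MU_PER_PMOL
    elif insulin_units != "pmol":
        raise ValueError(f"unknown insulin_units {insulin_units!r}")
    out = glucose * insulin / 22.5
    return float(out) if out.ndim == 0 else out


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL estimate in mmol/L: ``tc - hdl - tg/2.2``.

    Valid for triglycerides below 4.5 mmol/L; above that the value is still
    returned but a :class:`FriedewaldValidityWarning` is issued.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tg >= 4.5):
        warnings.warn(
            "triglycerides >= 4.5 mmol/L: Friedewald LDL outside validity range",
            FriedewaldValidityWarning,
            stacklevel=2,
        )
    out = tc - hdl - tg / 2.2
    return float(out) if out.ndim == 0 else out


def derived_ratios(panel: pd.DataFrame) -> pd.DataFrame:
    """Total:HDL cholesterol ratio and waist:height ratio per participant."""
    if np.any(panel["hdl"].to_numpy() <= 0) or np.any(panel["height"].to_numpy() <= 0):
        raise ValueError("hdl and height must be positive")
    return pd.DataFrame(
        {
            "tc_hdl": panel["tc"] / panel["hdl"],
            "waist_height": panel["waist"] / panel["height"],
        },
        index=panel.index,
    )


def _component_table(panel: pd.DataFrame, insulin_units: str) -> pd.DataFrame:
    ratios = derived_ratios(panel)
    return pd.DataFrame(
        {
            "sbp": panel["sbp"].astype(float),
            "tg": panel["tg"].astype(float),
            "tc_hdl": ratios["tc_hdl"],
            "homa": homa(panel["glucose"], panel["insulin"], insulin_units),
            "waist_height": ratios["waist_height"],
            "andersen": panel["andersen"].astype(float),
        },
        index=panel.index,
    )


class CompositeCardioScore(BaseEstimator, TransformerMixin):
    """Sex/age-adjusted composite cardiometabolic risk score.

    ``fit`` learns, over the analytic sample, a least-squares adjustment of
    each component on sex (indicator) and age (years), and the mean/SD of the
    resulting residuals.  ``transform`` returns the six z-scored residuals
    (Andersen negated) and their mean as ``composite``.

    Parameters
    ----------
    insulin_units : str
        Passed to :func:`homa` (``"pmol"`` applies the printed formula to the
        insulin column as-is).
    """

    def __init__(self, insulin_units: str = "pmol"):
        self.insulin_units = insulin_units

    def _design(self, panel: pd.DataFrame) -> np.ndarray:
        sex = panel["sex"].astype(float).to_numpy()
        age = panel["age"].astype(float).to_numpy()
        return np.column_stack([np.ones(len(panel)), sex, age])

    def fit(self, panel: pd.DataFrame, y=None):
        panel = self._validate_panel(panel)
        comp = _component_table(panel, self.insulin_units)
        Z = self._design(panel)
        # adjustment: least-squares of each component on (1, sex, age)
        beta, *_ = np.linalg.lstsq(Z, comp.to_numpy(), rcond=None)
        resid = comp.to_numpy() - Z @ beta
        sd = resid.std(axis=0, ddof=1)
        # a component constant (or sex/age-determined) leaves only float dust
        scale = np.abs(comp.to_numpy()).mean(axis=0) + 1.0
        degenerate = sd <= 1e-10 * scale
        if degenerate.any():
            bad = [c for c, d in zip(COMPOSITE_COMPONENTS, degenerate) if d]
            raise ValueError(f"degenerate (constant) component(s) after adjustment: {bad}")
        self.adjust_coef_ = pd.DataFrame(
            beta, index=["intercept", "sex", "age"], columns=COMPOSITE_COMPONENTS
        )
        self.resid_mean_ = pd.Series(resid.mean(axis=0), index=COMPOSITE_COMPONENTS)
        self.resid_sd_ = pd.Series(sd, index=COMPOSITE_COMPONENTS)
        self.n_participants_ = len(panel)
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        panel = self._validate_panel(panel)
        comp = _component_table(panel, self.insulin_units)
        resid = comp.to_numpy() - self._design(panel) @ self.adjust_coef_.to_numpy()
        z = (resid - self.resid_mean_.to_numpy()) / self.resid_sd_.to_numpy()
        out = pd.DataFrame(
            z, columns=[f"z_{c}" for c in COMPOSITE_COMPONENTS], index=panel.index
        )
        out["z_andersen"] *= -1.0  # fitness is protective: reverse before averaging
        out.insert(0, "id", panel["id"].to_numpy())
        out["composite"] = out[[f"z_{c}" for c in COMPOSITE_COMPONENTS]].mean(axis=1)
        return out

    def _validate_panel(self, panel: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
        if missing:
            raise ValueError(f"panel is missing columns: {missing}")
        complete = panel[PANEL_COLUMNS].notna().all(axis=1)
        dropped = panel.index[~complete]
        if len(dropped):
            warnings.warn(
                f"excluding {len(dropped)} participant(s) with incomplete panels",
                UserWarning,
                stacklevel=2,
            )
        panel = panel.loc[complete]
        if len(panel) < 10:
            raise ValueError("need at least 10 complete panels")
        if panel["sex"].nunique() < 2:
            raise ValueError("both sexes must be present for the adjustment")
        return panel


def composite_score(panel: pd.DataFrame, insulin_units: str = "pmol") -> pd.DataFrame:
    """Fit-and-transform convenience over :class:`CompositeCardioScore`."""
    scorer = CompositeCardioScore(insulin_units=insulin_units)
    return scorer.fit(panel).transform(panel)
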