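"""Synthetic accelerometer intensity-spectrum datasets with planted structure.

Cohort accelerometry has a very particular explanatory-variable geometry:
active-intensity bins are strongly, positively inter-correlated (active
children are active across the whole spectrum), correlations decay with the
distance between bins on the intensity axis, the sedentary bin is negatively
correlated with everything else, and per participant the bins sum exactly to
wear time (closure).  The generator reproduces that geometry so every
downstream stage — compositional transforms, regression, latent-variable
modelling — can be exercised and calibrated against a known truth.

Mechanism: active-bin minutes are ``exp(log_mean_j + loading_j * F_i + e_ij)``
with a shared per-participant activity factor ``F_i ~ N(0,1)`` driving the
positive inter-correlation and an AR(1) perturbation ``e_ij`` across adjacent
bins (decay with bin distance).  The sedentary bin absorbs wear time minus
active time, which enforces closure and the negative sedentary correlation in
one stroke.  The outcome is a linear signature on the *standardized* bins
plus Gaussian noise, so effects are in SD units and directly comparable to
standardized regression and selectivity-ratio patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actigraphy import BinScheme, spectrum_scheme


class ConfigurationError(ValueError):
    """Inconsistent synthetic-data configuration."""


def default_log_means(n_active: int = 22) -> np.ndarray:
    """Log-scale locations for active bins, decaying across the spectrum.

    Calibrated to the magnitudes seen in waist-worn children's cohorts:
    tens of minutes/day in the light range down to well under a minute/day in
    the most vigorous bins.
    """
    return np.linspace(3.6, -4.2, n_active)


def default_effect_vector(n_bins: int = 23) -> np.ndarray:
    """Planted outcome signature across the spectrum.

    Weak positive (unfavourable) effect for the sedentary bin, null through
    the light/moderate range, then a monotone ramp to -0.4 SD for the most
    vigorous bins — the qualitative shape cohort analyses report.
    """
    eff = np.zeros(n_bins)
    eff[0] = 0.1
    start = max(1, int(round(n_bins * 10 / 23)))  # null through the low/moderate range
    eff[start:] = np.linspace(0.0, -0.4, n_bins - start + 1)[1:]
    return eff


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration; defaults mirror the cohort conditions."""

    n_participants: int = 841
    bin_scheme: BinScheme = field(default_factory=spectrum_scheme)
    wear_minutes_mean: float = 795.0
    wear_minutes_sd: float = 56.0
    log_mean: np.ndarray | None = None  # per active bin (n_bins - 1)
    log_sd: float = 0.6
    latent_loading: np.ndarray | float = 0.35  # per active bin or scalar
    ar_rho: float = 0.85
    sed_anticorrelation: bool = True
    effect_vector: np.ndarray | None = None  # per bin (incl. sedentary)
    noise_sd: float = 4.5
    seed: int = 0

    def resolved(self) -> "SyntheticConfig":
        """Fill derived defaults and validate invariants."""
        d = self.bin_scheme.n_bins
        log_mean = (
            default_log_means(d - 1) if self.log_mean is None else np.asarray(self.log_mean, float)
        )
        effect = (
            default_effect_vector(d)
            if self.effect_vector is None
            else np.asarray(self.effect_vector, float)
        )
        loading = np.broadcast_to(
            np.asarray(self.latent_loading, float), (d - 1,)
        ).copy()
        cfg = replace(
            self, log_mean=log_mean, effect_vector=effect, latent_loading=loading
        )
        if cfg.n_participants < 2 * d:
            raise ConfigurationError(
                f"need n_participants >= {2 * d} for {d} bins, got {cfg.n_participants}"
            )
        if cfg.log_sd <= 0:
            raise ConfigurationError("log_sd must be positive")
        if cfg.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if len(log_mean) != d - 1:
            raise ConfigurationError("log_mean must have one entry per active bin")
        if len(effect) != d:
            raise ConfigurationError("effect_vector length must equal the number of bins")
        if not -1 < cfg.ar_rho < 1:
            raise ConfigurationError("ar_rho must lie in (-1, 1)")
        return cfg


@dataclass
class SyntheticDataset:
    """Profiles, matching outcome (and optional panel), and the planted truth."""

    profiles: pd.DataFrame  # id, one column per bin, wear_minutes
    outcome: pd.Series  # composite-score-like outcome, index-aligned
    truth: dict
    panel: pd.DataFrame | None = None

    @property
    def bin_columns(self) -> list:
        drop = {"id", "wear_minutes"}
        return [c for c in self.profiles.columns if c not in drop]

    def X(self) -> np.ndarray:
        return self.profiles[self.bin_columns].to_numpy()


def _ar1_noise(rng: np.random.Generator, n: int, k: int, rho: float, sd: float) -> np.ndarray:
    """AR(1) process across the k bins, independently per participant row."""
    eps = np.empty((n, k))
    innov = rng.standard_normal((n, k))
    eps[:, 0] = innov[:, 0]
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, k):
        eps[:, j] = rho * eps[:, j - 1] + scale * innov[:, j]
    return sd * eps


def generate_spectrum_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Draw a synthetic cohort of intensity profiles and outcomes.

    Closure holds by construction: per participant, bin minutes sum exactly
    to wear time.  Identical configs (including seed) give identical data.
    """
    cfg = (config or SyntheticConfig()).resolved()
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_participants, cfg.bin_scheme.n_bins
    wear = np.clip(
        rng.normal(cfg.wear_minutes_mean, cfg.wear_minutes_sd, n),
        0.25 * cfg.wear_minutes_mean,
        None,
    )
    factor = rng.standard_normal(n)
    eps = _ar1_noise(rng, n, d - 1, cfg.ar_rho, cfg.log_sd)
    active = np.exp(cfg.log_mean[None, :] + cfg.latent_loading[None, :] * factor[:, None] + eps)
    if cfg.sed_anticorrelation:
        tot = active.sum(axis=1)
        over = tot > wear
        if over.any():  # proportional shrink keeps closure feasible
            active[over] *= (wear[over] / tot[over])[:, None]
            tot = active.sum(axis=1)
        sed = np.maximum(wear - tot, 0.0)  # floor float dust from the shrink
        minutes = np.column_stack([sed, active])
        wear = minutes.sum(axis=1)
    else:
        sed = np.exp(
            np.log(cfg.wear_minutes_mean * 0.7) + 0.05 * rng.standard_normal(n)
        )
        minutes = np.column_stack([sed, active])
        wear = minutes.sum(axis=1)
    mu = minutes.mean(axis=0)
    sd = minutes.std(axis=0, ddof=1)
    z = (minutes - mu) / sd
    y = z @ cfg.effect_vector + cfg.noise_sd * rng.standard_normal(n)
    labels = list(cfg.bin_scheme.labels)
    profiles = pd.DataFrame(minutes, columns=labels)
    profiles.insert(0, "id", [f"P{i:04d}" for i in range(n)])
    profiles["wear_minutes"] = wear
    return SyntheticDataset(
        profiles=profiles,
        outcome=pd.Series(y, name="outcome"),
        truth={"effect_vector": cfg.effect_vector.copy(), "seed": cfg.seed},
    )


# Table-1-like location/scale used when dressing the outcome up as a panel
_PANEL_MOMENTS = {
    "sbp": (105.2, 8.4, +1),
    "tg": (0.78, 0.38, +1),
    "tc": (4.46, 0.69, +1),
    "hdl": (1.59, 0.35, -1),
    "glucose": (4.98, 0.32, +1),
    "insulin": (55.0, 30.0, +1),
    "waist": (61.9, 7.5, +1),
    "andersen": (898.0, 103.0, -1),
}


def attach_panel(dataset: SyntheticDataset, loading: float = 0.7, seed: int | None = None) -> SyntheticDataset:
    """Dress the planted outcome up as a realistic participant panel.

    Each indicator is drawn as ``mean + sd * (sign * loading * y + noise)``
    so the recomputed composite score correlates strongly with the planted
    outcome; height and age are signal-free.  Values are clipped away from
    zero to respect physiological positivity.
    """
    rng = np.random.default_rng(dataset.truth["seed"] + 104729 if seed is None else seed)
    y = (dataset.outcome - dataset.outcome.mean()) / dataset.outcome.std(ddof=1)
    n = len(y)
    resid_scale = np.sqrt(max(1.0 - loading**2, 0.0))
    cols = {"id": dataset.profiles["id"].to_numpy()}
    cols["sex"] = rng.integers(0, 2, n)
    cols["age"] = rng.normal(10.2, 0.3, n)
    cols["height"] = rng.normal(142.9, 6.7, n)
    for name, (mu, sd, sign) in _PANEL_MOMENTS.items():
        z = sign * loading * y.to_numpy() + resid_scale * rng.standard_normal(n)
        cols[name] = np.clip(mu + sd * z, 0.05 * mu, None)
    panel = pd.DataFrame(cols)
    # keep lipid ordering physiological
    panel["hdl"] = np.minimum(panel["hdl"], 0.9 * panel["tc"])
    dataset.panel = panel
    return dataset


def generate_epoch_series(
    n_days: int, wear_pattern: list, seed: int = 0, participant_id="S0001", start_date="2014-09-01"
) -> pd.DataFrame:
    """Build a 1-s epoch stream from a daily block specification.

    ``wear_pattern`` is a list of ``(start, end, level)`` blocks tiling
    00:00-24:00 each day, with times as "HH:MM" strings and ``level`` the
    counts per second for that block (0 for non-wear).  ``level`` may be a
    ``(mean, "poisson")`` pair to draw Poisson counts around a mean instead
    of a constant.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    sec_per_day = 86400
    covered = np.zeros(sec_per_day, dtype=bool)
    blocks = []
    for start, end, level in wear_pattern:
        s = int(pd.to_timedelta(start + ":00").total_seconds())
        e = sec_per_day if end in ("24:00", "00:00") else int(
            pd.to_timedelta(end + ":00").total_seconds()
        )
        if e <= s:
            raise ConfigurationError(f"block {start}-{end} is empty or reversed")
        if covered[s:e].any():
            raise ConfigurationError(f"block {start}-{end} overlaps another block")
        covered[s:e] = True
        blocks.append((s, e, level))
    if not covered.all():
        raise ConfigurationError("blocks must tile the full day 00:00-24:00")
    rng = np.random.default_rng(seed)
    day_counts = []
    for _ in range(n_days):
        day = np.zeros(sec_per_day, dtype=np.int64)
        for s, e, level in blocks:
            if isinstance(level, tuple) and level[1] == "poisson":
                day[s:e] = rng.poisson(level[0], e - s)
            else:
                if level < 0:
                    raise ConfigurationError("count levels must be >= 0")
                day[s:e] = int(level)
        day_counts.append(day)
    counts = np.concatenate(day_counts)
    t0 = pd.Timestamp(start_date)
    timestamps = t0 + pd.to_timedelta(np.arange(n_days * sec_per_day), unit="s")
    return pd.DataFrame(
        {"id": participant_id, "timestamp": timestamps, "counts": counts}
    )


def plant_two_variable_closure(n: int, total: float, seed: int = 0) -> pd.DataFrame:
    """Two-part time budget with a constant row sum.

    The minimal closed dataset: with only two behaviours sharing a fixed
    total, every minute in one is a minute out of the other, so their
    Pearson correlation is exactly -1.
    """
    if n < 3:
        raise ConfigurationError("need n >= 3 rows for a defined correlation")
    if total <= 0:
        raise ConfigurationError("total must be positive")
    rng = np.random.default_rng(seed)
    a = total * rng.beta(4, 4, n)
    return pd.DataFrame({"part_a": a, "part_b": total - a})


def dataset_to_csv(dataset: SyntheticDataset, out_dir) -> dict:
    """Write profiles (+ outcome + truth columns) and any panel as CSV."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof = dataset.profiles.copy()
    prof["outcome"] = dataset.outcome.to_numpy()
    for j, e in enumerate(dataset.truth["effect_vector"]):
        prof[f"truth_effect_{j}"] = e
    paths = {"profiles": out / "profiles.csv"}
    prof.to_csv(paths["profiles"], index=False)
    if dataset.panel is not None:
        paths["panel"] = out / "panel.csv"
        dataset.panel.to_csv(paths["panel"], index=False)
    return paths
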