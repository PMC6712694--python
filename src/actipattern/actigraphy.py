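"""Epoch-level accelerometer processing into per-participant intensity profiles.

Count streams are 1-second vertical-axis epochs.  Processing follows the
standard waist-worn children's protocol: restrict to 06:00-23:59, flag runs of
at least 60 min of consecutive zero counts as non-wear, require >= 8 h wear
per day and >= 4 valid days per participant, and classify each wear second
against counts-per-minute (cpm) cut points by scaling the 1-s count by 60.

Two bin schemes are built in: the traditional 4-category Evenson scheme
(SED 0-99, LPA 100-2295, MPA 2296-4011, VPA >= 4012 cpm) and a 23-bin
intensity spectrum (0-99, 100-249, 250-499, 500-999, then 500-cpm steps up to
>= 10000 cpm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NONWEAR_RUN_S = 3600  # >= 60 min of consecutive zeros
DAY_START = "06:00:00"
DAY_END = "23:59:59"
MIN_WEAR_MIN_PER_DAY = 480.0  # >= 8 h/day
MIN_VALID_DAYS = 4
GUIDELINE_MVPA_MIN = 60.0


class InvalidWearError(ValueError):
    """Participant has no valid wear days; profile undefined."""


@dataclass(frozen=True)
class BinScheme:
    """Named set of ascending cpm lower bounds; last bin unbounded above."""

    name: str
    edges: tuple = ()
    labels: tuple = ()

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 2 or edges[0] != 0 or any(
            b <= a for a, b in zip(edges, edges[1:])
        ):
            raise ValueError("edges must start at 0 and be strictly increasing")
        object.__setattr__(self, "edges", edges)
        if not self.labels:
            labels = []
            for a, b in zip(edges, edges[1:]):
                labels.append(f"{a:.0f}-{b - 1:.0f}")
            labels.append(f">={edges[-1]:.0f}")
            object.__setattr__(self, "labels", tuple(labels))
        elif len(self.labels) != len(edges):
            raise ValueError("labels must match the number of bins")

    @property
    def n_bins(self) -> int:
        return len(self.edges)


def traditional_scheme() -> BinScheme:
    """Evenson cut points: SED, LPA, MPA, VPA."""
    return BinScheme(
        name="traditional",
        edges=(0, 100, 2296, 4012),
        labels=("SED", "LPA", "MPA", "VPA"),
    )


def spectrum_scheme() -> BinScheme:
    """23 narrow intensity intervals from 0-99 to >= 10000 cpm."""
    edges = [0, 100, 250, 500] + list(range(1000, 10001, 500))
    return BinScheme(name="spectrum", edges=tuple(edges))


def get_scheme(name: str) -> BinScheme:
    if name == "traditional":
        return traditional_scheme()
    if name == "spectrum":
        return spectrum_scheme()
    raise ValueError(f"unknown bin scheme {name!r}")


@dataclass
class IntensityProfile:
    """Per-participant mean daily minutes in each intensity bin."""

    participant_id: object
    bin_minutes: np.ndarray
    wear_minutes: float
    n_valid_days: int
    scheme: BinScheme
    valid: bool = True
    overall_cpm: float = float("nan")

    def as_series(self) -> pd.Series:
        s = pd.Series(self.bin_minutes, index=list(self.scheme.labels))
        s["wear_minutes"] = self.wear_minutes
        s["n_valid_days"] = self.n_valid_days
        return s


def _validate_series(series: pd.DataFrame) -> pd.DataFrame:
    required = {"timestamp", "counts"}
    if not required <= set(series.columns):
        raise ValueError(f"epoch series needs columns {sorted(required)}")
    out = series.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"])
    counts = out["counts"].to_numpy()
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return out


def detect_nonwear(series: pd.DataFrame) -> np.ndarray:
    """Boolean wear mask per epoch; False inside zero runs of >= 60 min.

    Runs are evaluated on the stream as given (after any hour restriction),
    so a zero run spanning a gap in the record is treated as contiguous only
    if its epochs are contiguous rows.
    """
    series = _validate_series(series)
    counts = series["counts"].to_numpy()
    n = len(counts)
    if n == 0:
        return np.zeros(0, dtype=bool)
    zero = counts == 0
    # run-length encode the zero indicator
    change = np.flatnonzero(np.diff(zero.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    wear = np.ones(n, dtype=bool)
    for s, e in zip(starts, ends):
        if zero[s] and e - s >= NONWEAR_RUN_S:
            wear[s:e] = False
    return wear


def restrict_hours(series: pd.DataFrame) -> pd.DataFrame:
    """Keep only epochs with local time between 06:00:00 and 23:59:59."""
    series = _validate_series(series)
    t = series["timestamp"].dt
    lo = pd.to_timedelta(DAY_START)
    hi = pd.to_timedelta(DAY_END)
    delta = t.hour * 3600 + t.minute * 60 + t.second
    keep = (delta >= lo.total_seconds()) & (delta <= hi.total_seconds())
    return series.loc[keep].reset_index(drop=True)


def valid_days(series: pd.DataFrame, wear_mask: np.ndarray):
    """Valid calendar days (>= 480 wear minutes) and the participant flag.

    Returns ``(set of dates, participant_valid)`` where the participant is
    valid with >= 4 valid days.
    """
    series = _validate_series(series)
    if len(series) != len(wear_mask):
        raise ValueError("wear mask must align with the epoch series")
    if len(series) == 0:
        return set(), False
    dates = series["timestamp"].dt.date.to_numpy()
    wear_s = pd.Series(wear_mask.astype(int)).groupby(dates).sum()
    good = set(wear_s.index[wear_s / 60.0 >= MIN_WEAR_MIN_PER_DAY])
    return good, len(good) >= MIN_VALID_DAYS


def bin_profile(
    series: pd.DataFrame,
    wear_mask: np.ndarray,
    scheme: BinScheme,
    participant_id=None,
) -> IntensityProfile:
    """Classify wear epochs into cpm bins and average over valid days.

    Each 1-s count is scaled by 60 onto the cpm scale and assigned to the bin
    whose interval (closed-left, open-right; last unbounded) contains it.
    Daily bin seconds are converted to minutes and averaged over the valid
    days only.  Raises :class:`InvalidWearError` when no day meets the wear
    requirement, distinguishing exclusion from data errors.
    """
    series = _validate_series(series)
    if len(series) != len(wear_mask):
        raise ValueError("wear mask must align with the epoch series")
    if participant_id is None:
        participant_id = series["participant_id"].iloc[0] if "participant_id" in series else "unknown"
    dates = series["timestamp"].dt.date.to_numpy()
    days, participant_ok = valid_days(series, wear_mask)
    if not days:
        raise InvalidWearError(
            f"participant {participant_id!r}: no day reaches "
            f"{MIN_WEAR_MIN_PER_DAY:.0f} wear minutes"
        )
    keep = np.isin(dates, list(days)) & wear_mask
    cpm = series["counts"].to_numpy()[keep] * 60.0
    day = dates[keep]
    edges = np.asarray(scheme.edges)
    idx = np.searchsorted(edges, cpm, side="right") - 1
    uniq_days = np.unique(day)
    per_day = np.zeros((len(uniq_days), scheme.n_bins))
    for i, d in enumerate(uniq_days):
        sel = day == d
        per_day[i] = np.bincount(idx[sel], minlength=scheme.n_bins) / 60.0
    bin_minutes = per_day.mean(axis=0)
    wear_minutes = float(per_day.sum(axis=1).mean())
    total_counts = float(series["counts"].to_numpy()[keep].sum())
    return IntensityProfile(
        participant_id=participant_id,
        bin_minutes=bin_minutes,
        wear_minutes=wear_minutes,
        n_valid_days=len(uniq_days),
        scheme=scheme,
        valid=participant_ok,
        overall_cpm=total_counts / wear_minutes if wear_minutes > 0 else float("nan"),
    )


@dataclass
class ActivitySummary:
    mvpa_minutes: float
    overall_cpm: float
    meets_guideline: bool


def derive_summary(profile: IntensityProfile) -> ActivitySummary:
    """MVPA minutes, overall cpm and the 60-min/day guideline flag.

    Only defined for the traditional scheme: MVPA = MPA + VPA.
    """
    if profile.scheme.name != "traditional":
        raise ValueError("summary is defined for the traditional scheme")
    if profile.wear_minutes <= 0:
        raise ValueError("zero wear minutes: overall cpm undefined")
    labels = list(profile.scheme.labels)
    mvpa = float(
        profile.bin_minutes[labels.index("MPA")] + profile.bin_minutes[labels.index("VPA")]
    )
    return ActivitySummary(
        mvpa_minutes=mvpa,
        overall_cpm=profile.overall_cpm,
        meets_guideline=mvpa >= GUIDELINE_MVPA_MIN,
    )


def process_epochs(
    epochs: pd.DataFrame, scheme: BinScheme | str, require_valid: bool = True
) -> pd.DataFrame:
    """Full processing of a multi-participant epoch table into profiles.

    ``epochs`` has columns id, timestamp, counts.  Returns one row per
    participant with bin-minute columns, wear_minutes, n_valid_days and a
    valid flag; participants without any valid day are dropped with a reason
    when ``require_valid``.
    """
    if isinstance(scheme, str):
        scheme = get_scheme(scheme)
    rows = []
    for pid, grp in epochs.groupby("id", sort=True):
        series = grp.rename(columns={"id": "participant_id"}).reset_index(drop=True)
        series = restrict_hours(series)
        mask = detect_nonwear(series)
        try:
            prof = bin_profile(series, mask, scheme, participant_id=pid)
        except InvalidWearError:
            if require_valid:
                continue
            raise
        row = {"id": pid}
        row.update(dict(zip(scheme.labels, prof.bin_minutes)))
        row["wear_minutes"] = prof.wear_minutes
        row["n_valid_days"] = prof.n_valid_days
        row["valid"] = prof.valid
        row["overall_cpm"] = prof.overall_cpm
        rows.append(row)
    return pd.DataFrame(rows)
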