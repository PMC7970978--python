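"""Core CGM data model and I/O.

A continuous glucose monitor samples interstitial glucose every 5 minutes
(0.00333 Hz), i.e. 288 readings per day. :class:`GlucoseSeries` holds one
subject's recording snapped onto that regular grid, with an explicit boolean
gap mask for sensor dropouts — missing readings are never interpolated here;
downstream spectral reconstruction handles them explicitly.

Clock phases follow the day/night convention of ambulatory CGM studies:
day = 08:00-20:00, night = 20:00-08:00 (the night window spans midnight and
belongs to the day on which it opens at 20:00).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

SLOT_MINUTES = 5
SLOTS_PER_HOUR = 60 // SLOT_MINUTES          # 12
SLOTS_PER_DAY = 24 * SLOTS_PER_HOUR          # 288
HOURS_PER_DAY = 24

DAY_START_HOUR = 8    # day phase: 08:00-20:00
NIGHT_START_HOUR = 20  # night phase: 20:00-08:00 (+1 day)

GLUCOSE_FLOOR_MG_DL = 40.0

TIMESTAMP_COL = "timestamp"
GLUCOSE_COL = "glucose_mg_dl"
MISSING_COL = "missing"


class CgmFormatError(ValueError):
    """Input file does not have the expected CGM CSV shape."""


class CgmQualityError(ValueError):
    """Recording too incomplete to analyse (e.g. > 50% of grid slots missing)."""


class InsufficientDataError(ValueError):
    """Not enough non-missing samples for the requested computation."""


@dataclass
class GlucoseSeries:
    """One subject's CGM trace on the regular 5-minute grid.

    ``values`` holds glucose in mg/dL with ``np.nan`` at missing slots;
    ``gap_mask`` is the authoritative missingness indicator (True = missing).
    ``t0`` is the calendar time of slot 0, always on a 5-minute boundary.
    """

    subject_id: str
    t0: datetime
    values: np.ndarray
    gap_mask: np.ndarray
    n_days: int
    grid_step: timedelta = field(default=timedelta(minutes=SLOT_MINUTES))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        n = self.n_days * SLOTS_PER_DAY
        if self.values.shape != (n,) or self.gap_mask.shape != (n,):
            raise ValueError(
                f"series of {self.n_days} days must have {n} slots; "
                f"got values {self.values.shape}, gap_mask {self.gap_mask.shape}"
            )
        obs = self.values[~self.gap_mask]
        if obs.size and (not np.all(np.isfinite(obs)) or np.any(obs <= 0)):
            raise ValueError("non-missing glucose values must be finite and > 0 mg/dL")
        # keep values/NaN and the mask consistent
        self.values = self.values.copy()
        self.values[self.gap_mask] = np.nan

    @property
    def n_slots(self) -> int:
        return self.n_days * SLOTS_PER_DAY

    @property
    def n_observed(self) -> int:
        return int((~self.gap_mask).sum())

    @property
    def gap_fraction(self) -> float:
        return float(self.gap_mask.mean())

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.t0, periods=self.n_slots, freq=f"{SLOT_MINUTES}min")

    def observed(self) -> np.ndarray:
        """Non-missing glucose values, in grid order."""
        return self.values[~self.gap_mask]

    def slot_hour_of_day(self) -> np.ndarray:
        """Clock hour (0-23) of each grid slot."""
        start = self.t0.hour * SLOTS_PER_HOUR + self.t0.minute // SLOT_MINUTES
        slots = (start + np.arange(self.n_slots)) % SLOTS_PER_DAY
        return slots // SLOTS_PER_HOUR

    def hours_from_midnight(self) -> np.ndarray:
        """Continuous hours of each slot since 00:00 of the first recording day."""
        offset = self.t0.hour + self.t0.minute / 60.0
        return offset + np.arange(self.n_slots) * (SLOT_MINUTES / 60.0)

    def copy(self) -> "GlucoseSeries":
        return replace(self, values=self.values.copy(), gap_mask=self.gap_mask.copy())


@dataclass
class HourlySeries:
    """Hourly means of a :class:`GlucoseSeries` (24 points per recorded day)."""

    subject_id: str
    values: np.ndarray        # length 24 * n_days, NaN where the whole hour is missing
    hour_of_day: np.ndarray   # clock hour 0-23 per entry
    day_index: np.ndarray     # 0-based recording day per entry
    t0: datetime | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.hour_of_day = np.asarray(self.hour_of_day, dtype=int)
        self.day_index = np.asarray(self.day_index, dtype=int)
        if not (len(self.values) == len(self.hour_of_day) == len(self.day_index)):
            raise ValueError("hourly arrays must have equal length")
        if len(self.values) % HOURS_PER_DAY:
            raise ValueError("hourly series must contain 24 entries per recorded day")

    @property
    def n_days(self) -> int:
        return len(self.values) // HOURS_PER_DAY


@dataclass
class SubjectRecord:
    """Subject metadata attached to a recording."""

    subject_id: str
    group: str                      # "control" | "T1D"
    sex: str                        # "female" | "male"
    age: float
    weight: float | None = None     # kg
    height: float | None = None     # m
    bmi: float | None = None        # kg/m^2
    duration_diabetes: float | None = None   # years
    insulin_units_per_day: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "T1D"):
            raise ValueError(f"group must be 'control' or 'T1D', got {self.group!r}")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.weight is not None and self.height is not None:
            implied = self.weight / self.height**2
            if self.bmi is None:
                self.bmi = implied
            elif abs(self.bmi - implied) > 0.1:
                raise ValueError(
                    f"bmi {self.bmi:.2f} inconsistent with weight/height^2 = {implied:.2f}"
                )


@dataclass(frozen=True)
class PhaseWindow:
    """Half-open clock-hour window [start_hour, end_hour), wrapping at midnight."""

    label: str
    start_hour: int
    end_hour: int

    def contains_hour(self, hour: int | np.ndarray) -> np.ndarray:
        if self.start_hour < self.end_hour:
            return (hour >= self.start_hour) & (hour < self.end_hour)
        return (hour >= self.start_hour) | (hour < self.end_hour)


DAY_WINDOW = PhaseWindow("day", DAY_START_HOUR, NIGHT_START_HOUR)
NIGHT_WINDOW = PhaseWindow("night", NIGHT_START_HOUR, DAY_START_HOUR)
DEFAULT_PHASES = (DAY_WINDOW, NIGHT_WINDOW)


@dataclass
class PhaseSlice:
    """Samples of one series falling inside one clock phase."""

    label: str
    values: np.ndarray
    hour_of_day: np.ndarray
    day_index: np.ndarray   # for night, the day on which the 20:00 window opened


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _floor_to_grid(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor(f"{SLOT_MINUTES}min")


def read_cgm_csv(
    path,
    timestamp_col: str = TIMESTAMP_COL,
    glucose_col: str = GLUCOSE_COL,
    subject_id: str | None = None,
    n_days: int | None = None,
    max_gap_fraction: float = 0.5,
) -> GlucoseSeries:
    """Read a per-subject CGM CSV export onto the regular 5-minute grid.

    Rows are sorted, snapped to the grid anchored at the first sample's
    timestamp floored to a 5-minute boundary, duplicate timestamps averaged,
    and empty slots flagged in the gap mask.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (timestamp_col, glucose_col):
        if col not in df.columns:
            raise CgmFormatError(f"required column {col!r} not found in {path}")
    if subject_id is None:
        subject_id = str(path)
    df = df[[timestamp_col, glucose_col]].dropna()
    if df.empty:
        raise CgmQualityError(f"{path}: no usable samples")
    ts = pd.to_datetime(df[timestamp_col])
    order = np.argsort(ts.to_numpy(), kind="stable")
    ts = ts.iloc[order]
    glucose = df[glucose_col].to_numpy(dtype=float)[order]

    t0 = _floor_to_grid(ts.iloc[0])
    step = pd.Timedelta(minutes=SLOT_MINUTES)
    slots = np.asarray(
        np.round((ts - t0) / step).astype(int)
    )
    # duplicate timestamps collapse to their mean
    agg = pd.Series(glucose).groupby(slots).mean()
    if n_days is None:
        n_days = int(np.ceil((agg.index.max() + 1) / SLOTS_PER_DAY))
    n = n_days * SLOTS_PER_DAY
    values = np.full(n, np.nan)
    in_range = agg.index[(agg.index >= 0) & (agg.index < n)]
    values[in_range.to_numpy()] = agg.loc[in_range].to_numpy()
    gap_mask = np.isnan(values)
    if gap_mask.mean() > max_gap_fraction:
        raise CgmQualityError(
            f"{path}: {gap_mask.mean():.0%} of grid slots missing "
            f"(limit {max_gap_fraction:.0%})"
        )
    return GlucoseSeries(subject_id, t0.to_pydatetime(), values, gap_mask, n_days)


def write_cgm_csv(series: GlucoseSeries, path) -> None:
    """Write a normalized per-subject CSV on the regular grid with a missing flag."""
    df = pd.DataFrame(
        {
            TIMESTAMP_COL: series.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
            GLUCOSE_COL: series.values,
            MISSING_COL: series.gap_mask.astype(int),
        }
    )
    # default float formatting is repr-based and round-trips bit-exactly
    df.to_csv(path, index=False)


def read_normalized_csv(path, subject_id: str | None = None) -> GlucoseSeries:
    """Read back a CSV written by :func:`write_cgm_csv` (bit-exact round trip
    for gap-free series written at full precision)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (TIMESTAMP_COL, GLUCOSE_COL, MISSING_COL):
        if col not in df.columns:
            raise CgmFormatError(f"required column {col!r} not found in {path}")
    t0 = pd.to_datetime(df[TIMESTAMP_COL].iloc[0]).to_pydatetime()
    values = df[GLUCOSE_COL].to_numpy(dtype=float)
    gap_mask = df[MISSING_COL].to_numpy(dtype=bool)
    n_days = len(values) // SLOTS_PER_DAY
    return GlucoseSeries(subject_id or str(path), t0, values, gap_mask, n_days)


# ---------------------------------------------------------------------------
# aggregation and phase splitting
# ---------------------------------------------------------------------------

def hourly_average(series: GlucoseSeries) -> HourlySeries:
    """Average each clock hour's non-missing samples (24 points per day).

    Missing samples are excluded from each hourly mean; an hour with no
    observed sample at all is itself marked missing (NaN), never zero.
    """
    blocks = series.values.reshape(-1, SLOTS_PER_HOUR)
    counts = (~np.isnan(blocks)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(blocks, axis=1)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_hours = series.n_days * HOURS_PER_DAY
    start_hour = series.t0.hour  # t0 is grid-aligned; hour blocks follow t0
    idx = np.arange(n_hours)
    hour_of_day = (start_hour + idx) % HOURS_PER_DAY
    day_index = idx // HOURS_PER_DAY
    return HourlySeries(series.subject_id, means, hour_of_day, day_index, t0=series.t0)


def split_phases(
    series: GlucoseSeries | HourlySeries,
    windows: tuple[PhaseWindow, ...] = DEFAULT_PHASES,
) -> Mapping[str, PhaseSlice]:
    """Assign every sample to exactly one clock phase.

    Night windows span midnight; their samples carry the day index of the
    20:00 that opened the window.
    """
    if isinstance(series, GlucoseSeries):
        values = series.values
        hours = series.slot_hour_of_day()
        day_index = np.arange(series.n_slots) // SLOTS_PER_DAY
    else:
        values = series.values
        hours = series.hour_of_day
        day_index = series.day_index

    out: dict[str, PhaseSlice] = {}
    for w in windows:
        sel = w.contains_hour(hours)
        d = day_index[sel].copy()
        if w.start_hour > w.end_hour:  # wraps midnight: pre-dawn hours belong to prior day
            d = d - (hours[sel] < w.end_hour).astype(int)
        out[w.label] = PhaseSlice(w.label, values[sel], hours[sel], d)
    return out
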