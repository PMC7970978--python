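"""Per-subject glycemic summary metrics.

Mean, SD and CV of glucose over the whole recording; CGM-estimated HbA1c via
the affine ADAG-style mapping HbA1c% = (mean glucose + 46.7) / 28.7 and
HbA1c mmol/mol = 10.93 x HbA1c% - 23.5; time-in-range percentages with
strict clinical cut-offs (hyperglycemia > 180 mg/dL, hypoglycemia < 70
mg/dL); hour-of-day circadian profiles; and day/night dysglycemia
magnitudes.

All metrics operate on non-missing samples of the raw 5-minute grid by
default; missing samples are excluded, never imputed. SD uses the sample
(n-1) convention, configurable via ``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgm_core import (
    DEFAULT_PHASES,
    GlucoseSeries,
    HourlySeries,
    InsufficientDataError,
    PhaseWindow,
    split_phases,
)

HYPER_CUT_MG_DL = 180.0
HYPO_CUT_MG_DL = 70.0

# HbA1c% = (mean glucose + 46.7) / 28.7 ; mmol/mol = 10.93 * % - 23.5
HBA1C_GLUCOSE_OFFSET = 46.7
HBA1C_GLUCOSE_SLOPE = 28.7
HBA1C_MMOL_SLOPE = 10.93
HBA1C_MMOL_OFFSET = 23.5


@dataclass
class GlycemicSummary:
    subject_id: str
    mean_glucose: float
    sd_glucose: float
    cv_glucose: float        # fraction; multiply by 100 for %CV
    hba1c_percent: float
    hba1c_mmol: float
    pct_time_eu: float
    pct_time_hyper: float
    pct_time_hypo: float


@dataclass
class CircadianProfile:
    """Mean/SD of glucose per clock hour across recorded days."""

    subject_id: str
    hour: np.ndarray       # 0..23
    mean: np.ndarray       # NaN where no day contributed
    sd: np.ndarray
    n_days: np.ndarray     # contributing days per hour


@dataclass
class PhaseMagnitude:
    """Mean glucose of above-range and in-range samples within one phase.

    ``None`` magnitude means the category had no samples in that phase
    (flagged absent, never reported as zero).
    """

    subject_id: str
    phase: str
    hyper_magnitude: float | None
    eu_magnitude: float | None
    n_hyper: int
    n_eu: int


def estimated_hba1c(mean_glucose: float) -> tuple[float, float]:
    """CGM-estimated HbA1c in % and mmol/mol from mean glucose (mg/dL)."""
    if not mean_glucose > 0:
        raise ValueError(f"mean glucose must be > 0 mg/dL, got {mean_glucose}")
    pct = (mean_glucose + HBA1C_GLUCOSE_OFFSET) / HBA1C_GLUCOSE_SLOPE
    mmol = HBA1C_MMOL_SLOPE * pct - HBA1C_MMOL_OFFSET
    return pct, mmol


def variability(series: GlucoseSeries, ddof: int = 1) -> tuple[float, float, float]:
    """(mean, SD, CV) over all non-missing samples of the record."""
    obs = series.observed()
    if obs.size < 2:
        raise InsufficientDataError("variability needs >= 2 non-missing samples")
    mean = float(obs.mean())
    sd = float(obs.std(ddof=ddof))
    return mean, sd, sd / mean


def time_in_ranges(
    series: GlucoseSeries,
    hyper_cut: float = HYPER_CUT_MG_DL,
    hypo_cut: float = HYPO_CUT_MG_DL,
) -> tuple[float, float, float]:
    """Percent of non-missing samples euglycemic, hyperglycemic, hypoglycemic.

    Cut-offs are strict (> hyper_cut, < hypo_cut); a sample exactly at a
    cut-off counts as euglycemic. The three percentages sum to 100.
    """
    if not hypo_cut < hyper_cut:
        raise ValueError(f"hypo_cut {hypo_cut} must be < hyper_cut {hyper_cut}")
    obs = series.observed()
    if obs.size < 1:
        raise InsufficientDataError("time_in_ranges needs >= 1 non-missing sample")
    n = obs.size
    pct_hyper = 100.0 * (obs > hyper_cut).sum() / n
    pct_hypo = 100.0 * (obs < hypo_cut).sum() / n
    return 100.0 - pct_hyper - pct_hypo, pct_hyper, pct_hypo


def summarize(series: GlucoseSeries, **range_kwargs) -> GlycemicSummary:
    """Full glycemic summary for one subject."""
    mean, sd, cv = variability(series)
    pct, mmol = estimated_hba1c(mean)
    eu, hyper, hypo = time_in_ranges(series, **range_kwargs)
    return GlycemicSummary(series.subject_id, mean, sd, cv, pct, mmol, eu, hyper, hypo)


def circadian_profile(series: HourlySeries) -> CircadianProfile:
    """Per clock-hour mean/SD of hourly glucose across recorded days."""
    hours = np.arange(24)
    mean = np.full(24, np.nan)
    sd = np.full(24, np.nan)
    n_days = np.zeros(24, dtype=int)
    for h in hours:
        vals = series.values[series.hour_of_day == h]
        vals = vals[~np.isnan(vals)]
        n_days[h] = vals.size
        if vals.size:
            mean[h] = vals.mean()
            sd[h] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return CircadianProfile(series.subject_id, hours, mean, sd, n_days)


def phase_magnitudes(
    series: GlucoseSeries,
    windows: tuple[PhaseWindow, ...] = DEFAULT_PHASES,
    hyper_cut: float = HYPER_CUT_MG_DL,
    hypo_cut: float = HYPO_CUT_MG_DL,
) -> dict[str, PhaseMagnitude]:
    """Per phase, the mean of above-range samples (hyperglycemia magnitude)
    and of in-range samples (euglycemia magnitude)."""
    out: dict[str, PhaseMagnitude] = {}
    for label, sl in split_phases(series, windows).items():
        vals = sl.values[~np.isnan(sl.values)]
        hyper = vals[vals > hyper_cut]
        eu = vals[(vals >= hypo_cut) & (vals <= hyper_cut)]
        out[label] = PhaseMagnitude(
            subject_id=series.subject_id,
            phase=label,
            hyper_magnitude=float(hyper.mean()) if hyper.size else None,
            eu_magnitude=float(eu.mean()) if eu.size else None,
            n_hyper=int(hyper.size),
            n_eu=int(eu.size),
        )
    return out
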