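"""Seeded synthetic CGM cohort generator.

Emulates 6-day CGM recordings with the signal structure the downstream
analyses assume: a baseline glucose level, a circadian (24 h) sinusoid, one
or more infradian (multi-day) sinusoids, post-meal excursions with
exponential decay, AR(1) sensor noise, an optional random-walk drift (the
non-stationary regime) and geometrically distributed sensor-dropout gaps.

With ``drift_sd = 0`` and ``noise_ar1 < 1`` the generated process is
covariance-stationary by construction; with ``drift_sd > 0`` it contains a
unit root. Each profile also records its true dominant infradian period so
spectral recovery can be checked against ground truth.

Group defaults encode the qualitative contrasts of a T1D-vs-control CGM
cohort (higher mean, SD and oscillation energy in T1D) with anthropometry
drawn from typical adult clinic values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cgm_core import (
    GLUCOSE_FLOOR_MG_DL,
    SLOTS_PER_DAY,
    SLOTS_PER_HOUR,
    GlucoseSeries,
    SubjectRecord,
    write_cgm_csv,
)


class DegenerateProfileError(ValueError):
    """Profile parameters force > 10% of samples onto the physiological floor."""


@dataclass
class SubjectProfile:
    """Generative parameters for one synthetic subject's CGM trace."""

    group: str = "control"
    sex: str = "female"
    baseline_mg_dl: float = 95.0
    circadian_amplitude: float = 10.0
    circadian_phase_rad: float = 0.0
    # (period_days, amplitude_mg_dl, phase_rad)
    infradian_components: Sequence[tuple[float, float, float]] = field(default_factory=list)
    meal_times: Sequence[float] = (8.0, 13.5, 20.0)   # clock hours
    meal_amplitude: float = 30.0
    meal_decay: float = 90.0                          # minutes
    noise_sd: float = 5.0
    noise_ar1: float = 0.8
    drift_sd: float = 0.0                             # mg/dL per 5-min step
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.circadian_amplitude < 0 or self.meal_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes and noise_sd must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if not 0 <= self.dropout_rate < 0.5:
            raise ValueError("dropout_rate must lie in [0, 0.5)")
        if any(a < 0 for _, a, _ in self.infradian_components):
            raise ValueError("infradian amplitudes must be >= 0")

    @property
    def is_nonstationary(self) -> bool:
        return self.drift_sd > 0

    @property
    def dominant_infradian_period(self) -> float | None:
        """True period (days) of the largest-amplitude infradian component."""
        comps = [(p, a) for p, a, _ in self.infradian_components if a > 0]
        if not comps:
            return None
        return max(comps, key=lambda pa: pa[1])[0]


def simulate_subject(
    profile: SubjectProfile,
    n_days: int = 6,
    subject_id: str = "synthetic",
    t0: datetime | None = None,
) -> GlucoseSeries:
    """Simulate one subject's CGM trace on the 5-minute grid.

    Deterministic given (profile, n_days): all randomness flows from
    ``profile.seed``.
    """
    rng = np.random.default_rng(profile.seed)
    n = n_days * SLOTS_PER_DAY
    t_hours = np.arange(n) * (5.0 / 60.0)  # recording starts at midnight
    clock = t_hours % 24.0

    y = np.full(n, profile.baseline_mg_dl, dtype=float)
    y += profile.circadian_amplitude * np.sin(
        2 * np.pi * t_hours / 24.0 + profile.circadian_phase_rad
    )
    for period_days, amp, phase in profile.infradian_components:
        y += amp * np.sin(2 * np.pi * t_hours / (24.0 * period_days) + phase)

    # meal excursions: instantaneous rise, exponential decay (tau = meal_decay min)
    if profile.meal_amplitude > 0:
        tau_h = profile.meal_decay / 60.0
        for day in range(n_days):
            for meal_h in profile.meal_times:
                onset = day * 24.0 + meal_h
                amp = profile.meal_amplitude * rng.uniform(0.7, 1.3)
                after = t_hours >= onset
                y[after] += amp * np.exp(-(t_hours[after] - onset) / tau_h)

    # AR(1) sensor noise with stationary SD = noise_sd
    if profile.noise_sd > 0:
        innov_sd = profile.noise_sd * np.sqrt(1 - profile.noise_ar1**2)
        eps = rng.normal(0.0, innov_sd, n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, profile.noise_sd)
        for k in range(1, n):
            noise[k] = profile.noise_ar1 * noise[k - 1] + eps[k]
        y += noise

    # random-walk drift: the unit-root (non-stationary) regime
    if profile.drift_sd > 0:
        y += np.cumsum(rng.normal(0.0, profile.drift_sd, n))

    floored = y < GLUCOSE_FLOOR_MG_DL
    if floored.mean() > 0.10:
        raise DegenerateProfileError(
            f"{floored.mean():.0%} of samples at the {GLUCOSE_FLOOR_MG_DL} mg/dL floor"
        )
    y = np.maximum(y, GLUCOSE_FLOOR_MG_DL)

    gap_mask = _dropout_mask(rng, n, profile.dropout_rate)
    if t0 is None:
        t0 = datetime(2020, 1, 1, 0, 0)
    return GlucoseSeries(subject_id, t0, y, gap_mask, n_days)


def _dropout_mask(
    rng: np.random.Generator, n: int, rate: float, mean_run: float = 6.0
) -> np.ndarray:
    """Geometrically distributed dropout runs covering ~``rate`` of slots."""
    mask = np.zeros(n, dtype=bool)
    if rate <= 0:
        return mask
    target = int(round(rate * n))
    guard = 0
    while mask.sum() < target and guard < 10 * n:
        start = int(rng.integers(0, n))
        run = int(rng.geometric(1.0 / mean_run))
        stop = min(start + run, n)
        mask[start:stop] = True
        guard += 1
    # never let a whole day go dark (gap filling needs anchors each day)
    for day in range(n // SLOTS_PER_DAY):
        sl = slice(day * SLOTS_PER_DAY, (day + 1) * SLOTS_PER_DAY)
        if mask[sl].all():
            keep = int(rng.integers(0, SLOTS_PER_DAY))
            mask[day * SLOTS_PER_DAY + keep] = False
    return mask


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

@dataclass
class GroupParams:
    """Distributional parameters for one study group (control or T1D)."""

    baseline_mean: float
    baseline_sd: float
    circadian_amp_mean: float
    circadian_amp_sd: float
    infradian_amp_mean: float
    infradian_amp_sd: float
    infradian_periods: Sequence[float]   # candidate dominant periods, days
    meal_amp_mean: float
    meal_amp_sd: float
    noise_sd_mean: float
    noise_sd_sd: float
    noise_ar1: float
    dropout_rate: float
    nonstationary_frac: float
    drift_sd: float
    # anthropometry (mean, sd) keyed by sex
    age: dict = field(default_factory=dict)
    weight: dict = field(default_factory=dict)
    height: dict = field(default_factory=dict)
    duration: dict | None = None
    insulin: dict | None = None


def default_group_params(group: str) -> GroupParams:
    """Defaults reproducing the qualitative T1D-vs-control contrasts: higher
    baseline glucose, variability and oscillation energy in T1D."""
    if group == "control":
        return GroupParams(
            baseline_mean=95.0, baseline_sd=8.0,
            circadian_amp_mean=8.0, circadian_amp_sd=3.0,
            infradian_amp_mean=5.0, infradian_amp_sd=2.0,
            infradian_periods=(2.0, 3.0, 6.0),
            meal_amp_mean=30.0, meal_amp_sd=8.0,
            noise_sd_mean=7.0, noise_sd_sd=2.0,
            noise_ar1=0.8, dropout_rate=0.02,
            nonstationary_frac=0.25, drift_sd=1.5,
            age={"female": (40.2, 18.1), "male": (47.3, 19.6)},
            weight={"female": (71.0, 7.4), "male": (68.5, 7.0)},
            height={"female": (1.69, 0.09), "male": (1.71, 0.09)},
        )
    if group == "T1D":
        return GroupParams(
            baseline_mean=170.0, baseline_sd=20.0,
            circadian_amp_mean=20.0, circadian_amp_sd=6.0,
            infradian_amp_mean=30.0, infradian_amp_sd=8.0,
            infradian_periods=(2.0, 2.5, 3.0, 4.0, 5.0, 6.0),
            meal_amp_mean=55.0, meal_amp_sd=15.0,
            noise_sd_mean=22.0, noise_sd_sd=6.0,
            noise_ar1=0.85, dropout_rate=0.03,
            nonstationary_frac=0.10, drift_sd=2.5,
            age={"female": (34.7, 15.4), "male": (30.7, 14.4)},
            weight={"female": (63.5, 6.7), "male": (69.5, 13.3)},
            height={"female": (1.62, 0.08), "male": (1.70, 0.09)},
            duration={"female": (29.5, 12.6), "male": (23.4, 11.1)},
            insulin={"female": (5.0, 1.5), "male": (5.2, 1.9)},
        )
    raise ValueError(f"unknown group {group!r}")


@dataclass
class CohortSpec:
    """Counts per group x sex plus group parameter distributions and the
    master seed from which every subject's seed is derived."""

    n_control_female: int = 5
    n_control_male: int = 5
    n_t1d_female: int = 5
    n_t1d_male: int = 5
    n_days: int = 6
    master_seed: int = 0
    control: GroupParams = field(default_factory=lambda: default_group_params("control"))
    t1d: GroupParams = field(default_factory=lambda: default_group_params("T1D"))

    def __post_init__(self) -> None:
        for n in (self.n_control_female, self.n_control_male,
                  self.n_t1d_female, self.n_t1d_male):
            if n < 1:
                raise ValueError("all group x sex counts must be >= 1")

    @property
    def n_subjects(self) -> int:
        return (self.n_control_female + self.n_control_male
                + self.n_t1d_female + self.n_t1d_male)


@dataclass
class SimulatedSubject:
    """A generated subject: metadata, trace, and the ground-truth profile."""

    record: SubjectRecord
    series: GlucoseSeries
    profile: SubjectProfile


def _draw_profile(
    rng: np.random.Generator, params: GroupParams, group: str, sex: str, seed: int
) -> SubjectProfile:
    def pos(mean: float, sd: float, lo: float = 0.0) -> float:
        return float(max(lo, rng.normal(mean, sd)))

    n_comp = 1 + int(rng.random() < 0.3)     # 1-2 infradian components
    periods = rng.choice(params.infradian_periods, size=n_comp, replace=False)
    amps = np.sort([pos(params.infradian_amp_mean, params.infradian_amp_sd)
                    for _ in range(n_comp)])[::-1]
    comps = [
        (float(p), float(a), float(rng.uniform(0, 2 * np.pi)))
        for p, a in zip(periods, amps)
    ]
    nonstat = rng.random() < params.nonstationary_frac
    return SubjectProfile(
        group=group,
        sex=sex,
        baseline_mg_dl=pos(params.baseline_mean, params.baseline_sd, lo=60.0),
        circadian_amplitude=pos(params.circadian_amp_mean, params.circadian_amp_sd),
        circadian_phase_rad=float(rng.uniform(0, 2 * np.pi)),
        infradian_components=comps,
        meal_amplitude=pos(params.meal_amp_mean, params.meal_amp_sd),
        noise_sd=pos(params.noise_sd_mean, params.noise_sd_sd, lo=1.0),
        noise_ar1=params.noise_ar1,
        drift_sd=params.drift_sd if nonstat else 0.0,
        dropout_rate=params.dropout_rate,
        seed=seed,
    )


def _draw_record(
    rng: np.random.Generator, params: GroupParams, group: str, sex: str, subject_id: str
) -> SubjectRecord:
    def draw(spec: dict | None, lo: float, hi: float) -> float | None:
        if spec is None or sex not in spec:
            return None
        m, s = spec[sex]
        return float(np.clip(rng.normal(m, s), lo, hi))

    age = draw(params.age, 18.0, 80.0)
    weight = draw(params.weight, 40.0, 140.0)
    height = draw(params.height, 1.40, 2.05)
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        sex=sex,
        age=age if age is not None else 40.0,
        weight=weight,
        height=height,
        duration_diabetes=draw(params.duration, 0.5, 70.0),
        insulin_units_per_day=draw(params.insulin, 0.5, 20.0),
    )


def simulate_cohort(spec: CohortSpec) -> list[SimulatedSubject]:
    """Generate the full cohort; bit-reproducible from ``spec.master_seed``.

    Each subject draws from an independent seed-sequence child so subjects
    are individually reproducible regardless of cohort composition changes
    upstream of their index.
    """
    cells = [
        ("control", "female", spec.n_control_female, spec.control),
        ("control", "male", spec.n_control_male, spec.control),
        ("T1D", "female", spec.n_t1d_female, spec.t1d),
        ("T1D", "male", spec.n_t1d_male, spec.t1d),
    ]
    out: list[SimulatedSubject] = []
    idx = 0
    for group, sex, n, params in cells:
        for _ in range(n):
            ss = np.random.SeedSequence([spec.master_seed, idx])
            rng = np.random.default_rng(ss)
            subject_seed = int(ss.generate_state(1, np.uint32)[0]) % (2**31)
            sid = f"{'C' if group == 'control' else 'D'}{'F' if sex == 'female' else 'M'}{idx:03d}"
            profile = _draw_profile(rng, params, group, sex, subject_seed)
            record = _draw_record(rng, params, group, sex, sid)
            # a strongly drifting walk can pin at the glucose floor; retry the
            # same profile with a fresh noise seed a few times before giving up
            for attempt in range(8):
                try:
                    series = simulate_subject(profile, n_days=spec.n_days, subject_id=sid)
                    break
                except DegenerateProfileError:
                    if attempt == 7:
                        raise
                    reseed = np.random.SeedSequence([spec.master_seed, idx, attempt + 1])
                    profile.seed = int(reseed.generate_state(1, np.uint32)[0]) % (2**31)
            out.append(SimulatedSubject(record, series, profile))
            idx += 1
    return out


MANIFEST_COLUMNS = [
    "subject_id", "group", "sex", "age", "weight", "height", "bmi",
    "duration_years", "insulin_units", "path",
]


def write_cohort(subjects: list[SimulatedSubject], out_dir) -> Path:
    """Write per-subject normalized CSVs plus the cohort manifest; returns the
    manifest path. Ground-truth profiles go to a sidecar JSON for testing."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {}
    for s in subjects:
        fname = f"{s.record.subject_id}.csv"
        write_cgm_csv(s.series, out / fname)
        r = s.record
        rows.append({
            "subject_id": r.subject_id, "group": r.group, "sex": r.sex,
            "age": r.age, "weight": r.weight, "height": r.height, "bmi": r.bmi,
            "duration_years": r.duration_diabetes,
            "insulin_units": r.insulin_units_per_day, "path": fname,
        })
        truth[r.subject_id] = {
            "dominant_infradian_period": s.profile.dominant_infradian_period,
            "nonstationary": s.profile.is_nonstationary,
            "profile": _profile_dict(s.profile),
        }
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return manifest


def _profile_dict(profile: SubjectProfile) -> dict:
    d = asdict(profile)
    d["infradian_components"] = [list(c) for c in profile.infradian_components]
    d["meal_times"] = list(profile.meal_times)
    return d


def read_manifest(manifest_path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def record_from_manifest_row(row) -> SubjectRecord:
    def opt(v):
        return None if pd.isna(v) else float(v)

    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        sex=str(row["sex"]),
        age=float(row["age"]),
        weight=opt(row.get("weight")),
        height=opt(row.get("height")),
        bmi=opt(row.get("bmi")),
        duration_diabetes=opt(row.get("duration_years")),
        insulin_units_per_day=opt(row.get("insulin_units")),
    )
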