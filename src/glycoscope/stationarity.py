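"""Dickey-Fuller classification of glycemic signals.

A glucose trace is modelled as the AR(1) recursion y_t = rho * y_{t-1} + u_t.
A unit root (rho = 1) means random-walk, non-stationary behaviour; rho < 1
means a mean-reverting, deterministic oscillation. The Dickey-Fuller test
estimates rho by least squares on the first-difference form

    dy_t = (rho - 1) * y_{t-1} + u_t        (pure_AR1 variant)
    dy_t = c + (rho - 1) * y_{t-1} + u_t    (with_intercept variant)

and studentizes tau = (rho_hat - 1) / se(rho_hat). tau does not follow a t
distribution under the unit-root null, so p-values come from a seeded
Monte-Carlo calibration of tau under simulated random walks at the observed
length (left-tailed: small tau rejects the unit root).

Rejection of the unit root labels the signal *stationary* (deterministic
oscillation); failure to reject labels it *non_stationary* (random).

The pure_AR1 variant mirrors the bare recursion and is appropriate for
zero-mean signals; glucose has a large positive mean, for which the
with_intercept variant is correctly calibrated. Both share the same
Monte-Carlo machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm_core import GlucoseSeries, HourlySeries, InsufficientDataError, SubjectRecord

VARIANTS = ("pure_AR1", "with_intercept")

MIN_OBS = 20
DEFAULT_N_SIM = 10_000
DEFAULT_CALIBRATION_SEED = 20210311  # fixed so cached null tables are reproducible


class DegenerateInputError(ValueError):
    """Zero-variance (constant) input: the DF regression is undefined."""


@dataclass
class DickeyFullerResult:
    subject_id: str
    rho_hat: float
    tau_stat: float
    p_value: float
    label: str               # "stationary" | "non_stationary"
    n_obs: int
    variant: str
    alpha: float


@dataclass
class NullCalibration:
    """Seeded Monte-Carlo sample of tau under the unit-root null."""

    n_obs: int
    variant: str
    taus: np.ndarray         # sorted
    seed: int
    n_sim: int

    @classmethod
    def simulate(
        cls,
        n_obs: int,
        variant: str = "pure_AR1",
        n_sim: int = DEFAULT_N_SIM,
        seed: int = DEFAULT_CALIBRATION_SEED,
        chunk: int = 2000,
    ) -> "NullCalibration":
        """Simulate driftless random walks of the observed length and record
        the tau statistic of each."""
        if variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        rng = np.random.default_rng(seed)
        taus = np.empty(n_sim)
        done = 0
        while done < n_sim:
            m = min(chunk, n_sim - done)
            walks = np.cumsum(rng.standard_normal((m, n_obs)), axis=1)
            taus[done:done + m] = _tau_batch(walks, variant)
            done += m
        taus.sort()
        return cls(n_obs=n_obs, variant=variant, taus=taus, seed=seed, n_sim=n_sim)

    def p_value(self, tau: float) -> float:
        """Left-tailed empirical p-value with a +1 continuity correction."""
        k = int(np.searchsorted(self.taus, tau, side="right"))
        return (k + 1) / (self.n_sim + 1)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.taus, q))


def _tau_batch(Y: np.ndarray, variant: str) -> np.ndarray:
    """tau statistics for each row of Y via the first-difference regression."""
    x = Y[:, :-1]
    dy = np.diff(Y, axis=1)
    m = x.shape[1]
    if variant == "pure_AR1":
        sxx = np.einsum("ij,ij->i", x, x)
        b = np.einsum("ij,ij->i", x, dy) / sxx
        resid = dy - b[:, None] * x
        s2 = np.einsum("ij,ij->i", resid, resid) / (m - 1)
        se = np.sqrt(s2 / sxx)
    else:  # with_intercept
        xc = x - x.mean(axis=1, keepdims=True)
        dyc = dy - dy.mean(axis=1, keepdims=True)
        sxx = np.einsum("ij,ij->i", xc, xc)
        b = np.einsum("ij,ij->i", xc, dyc) / sxx
        resid = dyc - b[:, None] * xc
        s2 = np.einsum("ij,ij->i", resid, resid) / (m - 2)
        se = np.sqrt(s2 / sxx)
    return b / se


_CALIBRATION_CACHE: dict[tuple[int, str, int, int], NullCalibration] = {}


def get_calibration(
    n_obs: int,
    variant: str = "pure_AR1",
    n_sim: int = DEFAULT_N_SIM,
    seed: int = DEFAULT_CALIBRATION_SEED,
) -> NullCalibration:
    """Cached per-(length, variant) null calibration."""
    key = (n_obs, variant, n_sim, seed)
    if key not in _CALIBRATION_CACHE:
        _CALIBRATION_CACHE[key] = NullCalibration.simulate(n_obs, variant, n_sim, seed)
    return _CALIBRATION_CACHE[key]


def _extract_values(series) -> tuple[str, np.ndarray]:
    if isinstance(series, (GlucoseSeries, HourlySeries)):
        return series.subject_id, np.asarray(series.values, dtype=float)
    return "series", np.asarray(series, dtype=float)


def dickey_fuller(
    series,
    variant: str = "pure_AR1",
    alpha: float = 0.05,
    calibration: NullCalibration | None = None,
) -> DickeyFullerResult:
    """Classify one contiguous glucose signal as stationary / non-stationary.

    The input must be gap-free (apply spectral gap filling first); a constant
    series raises :class:`DegenerateInputError`. ``label`` is "stationary"
    exactly when the unit-root null is rejected (p < alpha).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    subject_id, y = _extract_values(series)
    if np.isnan(y).any():
        raise ValueError(
            "series contains missing samples; run spectral.gap_fill before dickey_fuller"
        )
    if y.size < MIN_OBS:
        raise InsufficientDataError(
            f"need >= {MIN_OBS} consecutive observations, got {y.size}"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant series: zero variance")

    tau = float(_tau_batch(y[None, :], variant)[0])
    x = y[:-1]
    dy = np.diff(y)
    if variant == "pure_AR1":
        rho = 1.0 + float(x @ dy / (x @ x))
    else:
        xc = x - x.mean()
        rho = 1.0 + float(xc @ (dy - dy.mean()) / (xc @ xc))

    if calibration is None:
        calibration = get_calibration(y.size, variant)
    elif calibration.n_obs != y.size or calibration.variant != variant:
        raise ValueError("calibration does not match series length/variant")
    p = calibration.p_value(tau)
    label = "stationary" if p < alpha else "non_stationary"
    return DickeyFullerResult(subject_id, rho, tau, p, label, y.size, variant, alpha)


def cohort_stationarity(
    results: list[DickeyFullerResult], records: list[SubjectRecord]
) -> pd.DataFrame:
    """Prevalence (%) of stationary / non-stationary labels per group x sex.

    Strata with no subjects are simply absent from the table; percentages in
    each present stratum sum to 100.
    """
    by_id = {r.subject_id: r for r in records}
    if set(res.subject_id for res in results) != set(by_id):
        raise ValueError("results and records do not pair one-to-one by subject_id")
    rows = []
    for res in results:
        rec = by_id[res.subject_id]
        rows.append({"group": rec.group, "sex": rec.sex, "label": res.label})
    df = pd.DataFrame(rows)
    out = []
    for (group, sex), sub in df.groupby(["group", "sex"]):
        n = len(sub)
        n_stat = int((sub["label"] == "stationary").sum())
        out.append({
            "group": group, "sex": sex, "n": n,
            "pct_stationary": 100.0 * n_stat / n,
            "pct_non_stationary": 100.0 * (n - n_stat) / n,
        })
    return pd.DataFrame(out).set_index(["group", "sex"]).sort_index()
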