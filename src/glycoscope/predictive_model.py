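"""Prediction of dysglycemia magnitude and timing from spectral features.

Each subject's maximum and minimum glycemia (mg/dL) and their occurrence
times (continuous hours from midnight of recording day 1, so a value such as
28.2 h means 04:13 on day 2) are regressed on the subject's Fourier
"weights" — amplitude and phase of the retained frequencies. Times are
log-transformed before fitting and exponentiated back for prediction.

The fitting procedure, per response:

1. draw ``n_repeats`` random subsamples of size ``n_subsample`` and fit an
   ordinary least-squares model on the full candidate feature set in each;
2. flag subjects whose standardized residual exceeds 3 in more than one
   subsample fit and exclude them (data points with unstable adjustment
   behaviour);
3. on the remaining subjects, backward stepwise elimination minimizing AIC
   starting from the full model;
4. prune remaining predictors with p >= alpha one at a time (worst first),
   refitting after each removal;
5. report coefficients, R^2, the F statistic and Shapiro-Wilk residual
   normality.

Everything is reproducible from (data, seed). Features are z-scored on the
full cohort before fitting; standardization parameters travel with the fit
so prediction applies the same scaling.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cgm_core import SLOT_MINUTES, GlucoseSeries
from .spectral import SpectralDecomposition

logger = logging.getLogger(__name__)

RESPONSES = ("g_max", "g_min", "log_t_max", "log_t_min")
LOG_RESPONSES = ("log_t_max", "log_t_min")


class ParameterError(ValueError):
    pass


class FeatureError(KeyError):
    pass


@dataclass
class EventTargets:
    """Observed extremes of one subject's (gap-filled) trace."""

    subject_id: str
    g_max: float
    g_min: float
    t_max: float        # hours since 00:00 of recording day 1
    t_min: float
    log_t_max: float
    log_t_min: float
    degenerate: bool = False


def extract_event_targets(series: GlucoseSeries) -> EventTargets:
    """Global extremes of a gap-filled series and their first-occurrence times."""
    if series.gap_mask.any():
        raise ValueError("extract_event_targets requires a gap-filled series")
    y = series.values
    if np.ptp(y) == 0:
        return EventTargets(series.subject_id, float(y[0]), float(y[0]),
                            np.nan, np.nan, np.nan, np.nan, degenerate=True)
    hours = series.hours_from_midnight()
    step_h = SLOT_MINUTES / 60.0
    i_max = int(np.argmax(y))
    i_min = int(np.argmin(y))
    # a slot-0 extreme at a midnight start would give t = 0; clamp to one step
    t_max = max(float(hours[i_max]), step_h)
    t_min = max(float(hours[i_min]), step_h)
    return EventTargets(
        subject_id=series.subject_id,
        g_max=float(y[i_max]), g_min=float(y[i_min]),
        t_max=t_max, t_min=t_min,
        log_t_max=float(np.log(t_max)), log_t_min=float(np.log(t_min)),
    )


def targets_frame(targets: list[EventTargets]) -> pd.DataFrame:
    rows = [t.__dict__ for t in targets if not t.degenerate]
    return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_feature_matrix(
    decs: list[SpectralDecomposition],
    min_select_frac: float = 0.25,
    max_frequencies: int | None = None,
    k_set: list[int] | None = None,
) -> pd.DataFrame:
    """One row per subject; columns are amplitude and phase of the retained
    Fourier frequencies (indexed by harmonic k of the recording length).

    Frequencies are retained when selected (high-energy) in at least
    ``min_select_frac`` of subjects, optionally capped at the
    ``max_frequencies`` with the largest cohort-mean PSD, or fixed
    explicitly via ``k_set``.
    """
    if not decs:
        raise ValueError("no decompositions given")
    n_freq = min(d.psd.size for d in decs)
    if k_set is None:
        sel = np.mean([d.selected[:n_freq] for d in decs], axis=0)
        ks = [k for k in range(1, n_freq) if sel[k] >= min_select_frac]
        if not ks:  # fall back to the strongest cohort-mean frequencies
            mean_psd = np.mean([d.psd[:n_freq] for d in decs], axis=0)
            ks = list(1 + np.argsort(mean_psd[1:])[::-1][:3])
        if max_frequencies is not None and len(ks) > max_frequencies:
            mean_psd = np.mean([d.psd[:n_freq] for d in decs], axis=0)
            ks = sorted(sorted(ks, key=lambda k: -mean_psd[k])[:max_frequencies])
    else:
        ks = sorted(k_set)
    rows = {}
    for d in decs:
        amp = d.amplitudes()
        ph = d.phases()
        row = {}
        for k in ks:
            row[f"amp_k{k}"] = amp[k]
            row[f"phase_k{k}"] = ph[k]
        rows[d.subject_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    response: str
    predictors: list[str]
    coefficients: dict[str, float]     # includes "const"; on standardized scale
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    r_squared: float
    f_stat: float
    df_model: int
    df_resid: int
    f_pvalue: float
    shapiro_w: float
    shapiro_p: float
    residuals: dict[str, float]
    excluded_subjects: list[str]
    n_subsample: int
    n_repeats: int
    alpha: float
    seed: int

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        return cls(**d)


def _ols(y: np.ndarray, X: pd.DataFrame):
    if X.shape[1]:
        Xc = sm.add_constant(X, has_constant="add")
    else:
        Xc = pd.DataFrame({"const": np.ones(len(y))}, index=X.index)
    return sm.OLS(y, Xc).fit()


def _standardized_residuals(res) -> np.ndarray:
    infl = res.get_influence()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return infl.resid_studentized_internal


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance and linearly dependent columns (logged)."""
    keep = [c for c in X.columns if X[c].std() > 1e-12]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    if X.shape[1] > 1:
        q, r = np.linalg.qr(X.to_numpy() - X.to_numpy().mean(axis=0))
        diag = np.abs(np.diag(r))
        dep = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-8 * max(diag.max(), 1)]
        if dep:
            dropped += dep
            X = X.drop(columns=dep)
    if dropped:
        logger.warning("dropped collinear/constant feature columns: %s", dropped)
    return X


def fit_predictive_model(
    features: pd.DataFrame,
    targets: pd.DataFrame | list[EventTargets],
    responses: tuple[str, ...] = RESPONSES,
    n_subsample: int | None = None,
    n_repeats: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
    resid_z: float = 3.0,
) -> dict[str, ModelFit]:
    """Run the full subsample / exclusion / AIC / pruning procedure for each
    response; returns one :class:`ModelFit` per response."""
    if isinstance(targets, list):
        targets = targets_frame(targets)
    common = features.index.intersection(targets.index)
    if len(common) < len(features) or len(common) < len(targets):
        logger.warning("features/targets only overlap on %d subjects", len(common))
    features = features.loc[common]
    targets = targets.loc[common]
    n = len(common)

    if n_subsample is None:
        n_subsample = 140 if n >= 150 else max(int(0.8 * n), 3)
    if n_subsample > n:
        raise ParameterError(
            f"n_subsample={n_subsample} exceeds cohort size {n}; "
            "pass a smaller value or a fraction of the cohort (e.g. int(0.8 * n))"
        )

    X_all = _drop_collinear(features.astype(float))
    mu = X_all.mean()
    sd = X_all.std(ddof=0).replace(0.0, 1.0)
    Z = (X_all - mu) / sd
    max_p = max(n_subsample - 2, 1)
    if Z.shape[1] > max_p:
        order = Z.var().sort_values(ascending=False).index[:max_p]
        logger.warning("capping candidate features at %d (subsample size %d)",
                       max_p, n_subsample)
        Z = Z[sorted(order)]

    fits: dict[str, ModelFit] = {}
    for r_i, response in enumerate(responses):
        if response not in targets.columns:
            raise ParameterError(f"targets frame lacks response column {response!r}")
        y = targets[response].astype(float)
        rng = np.random.default_rng(np.random.SeedSequence([seed, r_i]))

        # (1)-(2) repeated random subsamples; flag unstable points
        flags = pd.Series(0, index=Z.index)
        for _ in range(n_repeats):
            pick = rng.choice(n, size=n_subsample, replace=False)
            sub_idx = Z.index[np.sort(pick)]
            res = _ols(y.loc[sub_idx].to_numpy(), Z.loc[sub_idx])
            sr = _standardized_residuals(res)
            bad = sub_idx[np.abs(sr) > resid_z]
            flags.loc[bad] += 1
        excluded = list(flags.index[flags > 1])
        keep = flags.index.difference(excluded)
        Zk, yk = Z.loc[keep], y.loc[keep]

        # (3) backward stepwise minimizing AIC
        current = list(Zk.columns)
        best = _ols(yk.to_numpy(), Zk[current])
        improved = True
        while improved and current:
            improved = False
            trial_aics = []
            for c in current:
                reduced = [x for x in current if x != c]
                res = _ols(yk.to_numpy(), Zk[reduced])
                trial_aics.append((res.aic, c, res))
            trial_aics.sort(key=lambda t: t[0])
            if trial_aics[0][0] < best.aic:
                _, drop, best = trial_aics[0]
                current.remove(drop)
                improved = True

        # (4) p-value pruning, worst first
        while current:
            pvals = best.pvalues.drop("const", errors="ignore")
            worst = pvals.idxmax()
            if pvals.max() < alpha:
                break
            current.remove(worst)
            best = _ols(yk.to_numpy(), Zk[current])

        # (5) diagnostics
        resid = np.asarray(best.resid)
        if resid.size >= 3 and np.ptp(resid) > 0:
            sw = stats.shapiro(resid)
            shapiro_w, shapiro_p = float(sw.statistic), float(sw.pvalue)
        else:
            shapiro_w, shapiro_p = np.nan, np.nan
        params = best.params
        coef = {k: float(v) for k, v in params.items()}
        fits[response] = ModelFit(
            response=response,
            predictors=list(current),
            coefficients=coef,
            feature_means={c: float(mu[c]) for c in current},
            feature_sds={c: float(sd[c]) for c in current},
            r_squared=float(best.rsquared) if current else 0.0,
            f_stat=float(best.fvalue) if current else np.nan,
            df_model=int(best.df_model),
            df_resid=int(best.df_resid),
            f_pvalue=float(best.f_pvalue) if current else np.nan,
            shapiro_w=shapiro_w,
            shapiro_p=shapiro_p,
            residuals={sid: float(r) for sid, r in zip(keep, resid)},
            excluded_subjects=[str(s) for s in excluded],
            n_subsample=n_subsample,
            n_repeats=n_repeats,
            alpha=alpha,
            seed=seed,
        )
    return fits


# ---------------------------------------------------------------------------
# prediction and evaluation
# ---------------------------------------------------------------------------

@dataclass
class EventPrediction:
    subject_id: str
    g_max: float | None = None
    g_min: float | None = None
    t_max: float | None = None      # hours, back-transformed from log
    t_min: float | None = None
    consistent: bool = True         # g_max >= g_min where both predicted


def _predict_one(fit: ModelFit, row: pd.Series) -> float:
    val = fit.coefficients.get("const", 0.0)
    for p in fit.predictors:
        if p not in row.index:
            raise FeatureError(f"missing predictor column {p!r}")
        z = (float(row[p]) - fit.feature_means[p]) / fit.feature_sds[p]
        val += fit.coefficients[p] * z
    return float(val)


def predict_events(
    fits: dict[str, ModelFit], features: pd.DataFrame
) -> list[EventPrediction]:
    """Apply fitted models to each feature row; time responses are
    exponentiated back to hours. A predicted g_max below g_min is reported
    with ``consistent=False``, never silently reordered."""
    out = []
    for sid, row in features.iterrows():
        pred = EventPrediction(subject_id=str(sid))
        for response, fit in fits.items():
            val = _predict_one(fit, row)
            if response == "g_max":
                pred.g_max = val
            elif response == "g_min":
                pred.g_min = val
            elif response == "log_t_max":
                pred.t_max = float(np.exp(val))
            elif response == "log_t_min":
                pred.t_min = float(np.exp(val))
        if pred.g_max is not None and pred.g_min is not None:
            pred.consistent = pred.g_max >= pred.g_min
        out.append(pred)
    return out


def predictions_frame(preds: list[EventPrediction]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in preds]).set_index("subject_id")


def evaluate_fit(fit: ModelFit, targets: pd.DataFrame, features: pd.DataFrame) -> dict:
    """Recompute diagnostics of a fit on its post-exclusion fitting set."""
    keep = [s for s in targets.index if s not in set(fit.excluded_subjects)]
    keep = [s for s in keep if s in features.index]
    y = targets.loc[keep, fit.response].astype(float).to_numpy()
    yhat = np.array([_predict_one(fit, features.loc[s]) for s in keep])
    resid = y - yhat
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    if resid.size >= 3 and np.ptp(resid) > 0:
        sw = stats.shapiro(resid)
        w, p = float(sw.statistic), float(sw.pvalue)
    else:
        w, p = np.nan, np.nan
    hist, edges = np.histogram(resid, bins=min(20, max(5, resid.size // 10)))
    return {
        "response": fit.response,
        "n": len(keep),
        "r_squared": r2,
        "f_stat": fit.f_stat,
        "df_model": fit.df_model,
        "df_resid": fit.df_resid,
        "shapiro_w": w,
        "shapiro_p": p,
        "error_hist_counts": hist.tolist(),
        "error_hist_edges": edges.tolist(),
    }


def save_fits(fits: dict[str, ModelFit], path) -> None:
    payload = {r: f.to_dict() for r, f in fits.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_fits(path) -> dict[str, ModelFit]:
    with open(path) as fh:
        payload = json.load(fh)
    return {r: ModelFit.from_dict(d) for r, d in payload.items()}
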