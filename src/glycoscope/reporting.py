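"""End-to-end pipeline, cohort report and group comparisons.

``run_pipeline`` ties the stages together: cohort input (real CSVs or the
synthetic generator) -> raw-grid glycemic metrics -> spectral gap filling ->
Dickey-Fuller stationarity -> spectral decomposition -> predictive model ->
cohort report. Every stage writes its CSV/JSON artifact into the output
directory, all randomness flows from one master seed, and reruns with the
same config are bit-identical.

Between-group comparisons (two-way group x sex ANOVA, rank tests) are
delegated to statsmodels/scipy and attached to the report as annotations;
they are reporting conveniences, not part of the analysis chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import __version__
from .cgm_core import GlucoseSeries, SubjectRecord, read_normalized_csv
from .synthetic_cohort import (
    CohortSpec,
    SimulatedSubject,
    read_manifest,
    record_from_manifest_row,
    simulate_cohort,
    write_cohort,
)
from . import glycemic_metrics as gm
from . import spectral as sp
from . import stationarity as st
from . import predictive_model as pm

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject_id: str | None, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        super().__init__(
            f"stage {stage!r} failed"
            + (f" for subject {subject_id!r}" if subject_id else "")
            + f": {cause}"
        )


@dataclass
class PipelineConfig:
    """Single YAML-serializable configuration for a full run."""

    out_dir: str = "glycoscope_out"
    input_dir: str | None = None           # directory with manifest.csv, else synthetic
    master_seed: int = 0
    n_control_female: int = 5
    n_control_male: int = 5
    n_t1d_female: int = 5
    n_t1d_male: int = 5
    n_days: int = 6
    alpha: float = 0.05
    df_variant: str = "with_intercept"     # glucose has a nonzero mean
    threshold_mode: str = "absolute"
    threshold_au: float = sp.DEFAULT_THRESHOLD_AU
    threshold_quantile: float = 0.99
    hyper_cut: float = gm.HYPER_CUT_MG_DL
    hypo_cut: float = gm.HYPO_CUT_MG_DL
    pm_n_repeats: int = 40
    pm_n_subsample: int | None = None
    pm_max_frequencies: int = 4
    pm_min_select_frac: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the analysis-relevant configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class CohortReport:
    provenance: dict
    baseline: dict
    glycemic: dict
    time_in_range: dict
    stationarity: dict
    oscillation: dict
    total_power: dict
    predictive: dict
    comparisons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _load_cohort(config: PipelineConfig, out: Path):
    if config.input_dir is not None:
        manifest = read_manifest(Path(config.input_dir) / "manifest.csv")
        if manifest.empty:
            raise ValueError("manifest lists no subjects")
        records, series = [], []
        for _, row in manifest.iterrows():
            rec = record_from_manifest_row(row)
            s = read_normalized_csv(Path(config.input_dir) / row["path"], rec.subject_id)
            records.append(rec)
            series.append(s)
        return records, series
    spec = CohortSpec(
        n_control_female=config.n_control_female,
        n_control_male=config.n_control_male,
        n_t1d_female=config.n_t1d_female,
        n_t1d_male=config.n_t1d_male,
        n_days=config.n_days,
        master_seed=config.master_seed,
    )
    subjects = simulate_cohort(spec)
    write_cohort(subjects, out / "cohort")
    return [s.record for s in subjects], [s.series for s in subjects]


def _stage(name: str, subject_id: str | None = None):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, subject_id, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> CohortReport:
    """Execute the full analysis chain and write per-stage artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    with _stage("cohort"):
        records, raw_series = _load_cohort(config, out)
    by_id = {r.subject_id: r for r in records}

    # metrics on the raw grid (missing samples excluded, never imputed)
    summaries, magnitudes = [], []
    for s in raw_series:
        with _stage("glycemic_metrics", s.subject_id):
            summaries.append(
                gm.summarize(s, hyper_cut=config.hyper_cut, hypo_cut=config.hypo_cut)
            )
            magnitudes.append(
                gm.phase_magnitudes(s, hyper_cut=config.hyper_cut,
                                    hypo_cut=config.hypo_cut)
            )
    metrics_df = pd.DataFrame([m.__dict__ for m in summaries]).set_index("subject_id")
    for phase in ("day", "night"):
        metrics_df[f"{phase}_hyper_magnitude"] = [
            m[phase].hyper_magnitude for m in magnitudes
        ]
        metrics_df[f"{phase}_eu_magnitude"] = [m[phase].eu_magnitude for m in magnitudes]
    metrics_df = metrics_df.sort_index()
    metrics_df.to_csv(out / "metrics.csv", float_format="%.6f")

    # spectral gap fill feeds both the DF test and the FFT
    filled: list[GlucoseSeries] = []
    for s in raw_series:
        with _stage("gap_fill", s.subject_id):
            filled.append(sp.gap_fill(s))

    df_results = []
    for s in filled:
        with _stage("stationarity", s.subject_id):
            df_results.append(
                st.dickey_fuller(s, variant=config.df_variant, alpha=config.alpha)
            )
    st_df = pd.DataFrame([r.__dict__ for r in df_results]).set_index("subject_id")
    st_df = st_df.sort_index()
    st_df.to_csv(out / "stationarity.csv", float_format="%.6g")
    with _stage("stationarity"):
        st_prev = st.cohort_stationarity(df_results, records)

    decs = []
    for s in filled:
        with _stage("spectral", s.subject_id):
            decs.append(
                sp.decompose(s, threshold_au=config.threshold_au,
                             threshold_mode=config.threshold_mode,
                             quantile=config.threshold_quantile)
            )
    spectra_df = pd.DataFrame([
        {
            "subject_id": d.subject_id,
            "total_power": d.total_power,
            "max_period_days": d.max_period_days,
            "period_bin": sp.bin_max_period(d.max_period_days),
            "circadian": int(d.circadian_flag),
            "n_selected": int(d.selected.sum()),
        }
        for d in decs
    ]).set_index("subject_id").sort_index()
    spectra_df.to_csv(out / "spectra.csv", float_format="%.6f")
    with _stage("spectral"):
        osc_prev, power = sp.cohort_oscillation(decs, records)

    with _stage("predictive_model"):
        targets = [pm.extract_event_targets(s) for s in filled]
        tframe = pm.targets_frame(targets)
        tframe.to_csv(out / "events.csv", float_format="%.6f")
        features = pm.build_feature_matrix(
            decs, min_select_frac=config.pm_min_select_frac,
            max_frequencies=config.pm_max_frequencies,
        )
        features.to_csv(out / "features.csv", float_format="%.8f")
        fits = pm.fit_predictive_model(
            features, tframe,
            n_subsample=config.pm_n_subsample,
            n_repeats=config.pm_n_repeats,
            alpha=config.alpha,
            seed=config.master_seed,
        )
        pm.save_fits(fits, out / "model.json")
        preds = pm.predictions_frame(pm.predict_events(fits, features))
        preds.to_csv(out / "predictions.csv", float_format="%.6f")

    report = _build_report(config, records, metrics_df, st_prev, osc_prev, power, fits)
    with _stage("group_comparisons"):
        report.comparisons = group_comparisons(
            metrics_df, records,
            metrics=("mean_glucose", "sd_glucose", "cv_glucose", "hba1c_percent"),
        )
    _write_report(report, out)
    return report


def _group_table(metrics_df: pd.DataFrame, records: list[SubjectRecord], cols) -> dict:
    rec_df = pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, "sex": r.sex} for r in records]
    ).set_index("subject_id")
    joined = metrics_df.join(rec_df)
    table: dict = {}
    for (group, sex), sub in joined.groupby(["group", "sex"]):
        entry = {"n": int(len(sub))}
        for c in cols:
            vals = sub[c].dropna().astype(float)
            entry[c] = {
                "mean": float(vals.mean()) if len(vals) else None,
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        table[f"{group}/{sex}"] = entry
    return table


def _build_report(config, records, metrics_df, st_prev, osc_prev, power, fits) -> CohortReport:
    provenance = {
        "software": "glycoscope",
        "version": __version__,
        "master_seed": config.master_seed,
        "config_digest": config.digest(),
        "n_subjects": len(records),
    }
    baseline = _group_table(metrics_df, records, [])
    glycemic = _group_table(
        metrics_df, records,
        ["mean_glucose", "sd_glucose", "cv_glucose", "hba1c_percent", "hba1c_mmol"],
    )
    tir = _group_table(
        metrics_df, records, ["pct_time_eu", "pct_time_hyper", "pct_time_hypo"]
    )
    predictive = {
        r: {
            "predictors": f.predictors,
            "r_squared": f.r_squared,
            "f_stat": f.f_stat,
            "df_model": f.df_model,
            "df_resid": f.df_resid,
            "shapiro_w": f.shapiro_w,
            "shapiro_p": f.shapiro_p,
            "n_excluded": len(f.excluded_subjects),
        }
        for r, f in fits.items()
    }
    return CohortReport(
        provenance=provenance,
        baseline=baseline,
        glycemic=glycemic,
        time_in_range=tir,
        stationarity=json.loads(st_prev.reset_index().to_json(orient="records")),
        oscillation=json.loads(osc_prev.reset_index().to_json(orient="records")),
        total_power=json.loads(power.reset_index().to_json(orient="records")),
        predictive=predictive,
    )


def _write_report(report: CohortReport, out: Path) -> None:
    (out / "report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True, allow_nan=True)
    )
    lines = ["# Cohort report", ""]
    prov = report.provenance
    lines += [
        f"glycoscope {prov['version']} | master seed {prov['master_seed']} | "
        f"config {prov['config_digest']} | n = {prov['n_subjects']}",
        "",
        "## Glycemic summary (mean +/- SD per group/sex)",
    ]
    for stratum, entry in report.glycemic.items():
        parts = [f"n={entry['n']}"]
        for k, v in entry.items():
            if isinstance(v, dict) and v["mean"] is not None:
                parts.append(f"{k}={v['mean']:.1f}+/-{v['sd']:.1f}")
        lines.append(f"- {stratum}: " + ", ".join(parts))
    lines += ["", "## Stationarity prevalence (%)"]
    for row in report.stationarity:
        lines.append(
            f"- {row['group']}/{row['sex']} (n={row['n']}): "
            f"stationary {row['pct_stationary']:.1f}, "
            f"non-stationary {row['pct_non_stationary']:.1f}"
        )
    lines += ["", "## Dominant oscillation period prevalence (%)"]
    for row in report.oscillation:
        bins = ", ".join(
            f"{lbl}: {row[lbl]:.1f}" for lbl in sp.PERIOD_BIN_LABELS if row.get(lbl)
        )
        lines.append(
            f"- {row['group']}/{row['sex']} (n={row['n']}): {bins or 'none'}; "
            f"circadian {row['pct_circadian']:.1f}"
        )
    lines += ["", "## Predictive model"]
    for resp, d in report.predictive.items():
        lines.append(
            f"- {resp}: R^2={d['r_squared']:.3f}, F={d['f_stat']:.3g} "
            f"(df {d['df_model']},{d['df_resid']}), W={d['shapiro_w']:.3f} "
            f"(p={d['shapiro_p']:.3g}), predictors={d['predictors']}, "
            f"excluded={d['n_excluded']}"
        )
    (out / "report.md").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# between-group comparisons (delegated to standard routines)
# ---------------------------------------------------------------------------

def group_comparisons(
    metrics_df: pd.DataFrame,
    records: list[SubjectRecord],
    metrics: tuple[str, ...] = ("mean_glucose", "sd_glucose"),
    min_per_stratum: int = 2,
) -> dict:
    """Two-way (group x sex) ANOVA per metric via statsmodels, plus a
    group-wise Mann-Whitney test; strata below ``min_per_stratum`` subjects
    are skipped with a logged note."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rec_df = pd.DataFrame(
        [{"subject_id": r.subject_id, "group": r.group, "sex": r.sex} for r in records]
    ).set_index("subject_id")
    data = metrics_df.join(rec_df)
    counts = data.groupby(["group", "sex"]).size()
    if (counts < min_per_stratum).any() or len(counts) < 4:
        logger.warning("stratum too small for two-way ANOVA; comparisons skipped")
        return {"skipped": "stratum below minimum size"}
    out: dict = {}
    for m in metrics:
        if m not in data.columns:
            continue
        sub = data[[m, "group", "sex"]].dropna().rename(columns={m: "y"})
        model = smf.ols("y ~ C(group) * C(sex)", data=sub).fit()
        table = anova_lm(model, typ=2)
        ctrl = sub.loc[sub["group"] == "control", "y"]
        t1d = sub.loc[sub["group"] == "T1D", "y"]
        mw = sps.mannwhitneyu(t1d, ctrl, alternative="two-sided")
        out[m] = {
            "anova_F_group": float(table.loc["C(group)", "F"]),
            "anova_p_group": float(table.loc["C(group)", "PR(>F)"]),
            "anova_F_sex": float(table.loc["C(sex)", "F"]),
            "anova_p_sex": float(table.loc["C(sex)", "PR(>F)"]),
            "mannwhitney_U": float(mw.statistic),
            "mannwhitney_p": float(mw.pvalue),
            "t1d_minus_control_mean": float(t1d.mean() - ctrl.mean()),
        }
    return out
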