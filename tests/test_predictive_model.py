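"""Event-target extraction, subsample/AIC fitting, prediction contracts."""

import numpy as np
import pandas as pd
import pytest

from glycoscope import (
    build_feature_matrix,
    decompose,
    evaluate_fit,
    extract_event_targets,
    fit_predictive_model,
    predict_events,
)
from glycoscope.cgm_core import SLOTS_PER_DAY
from glycoscope.predictive_model import (
    ModelFit,
    ParameterError,
    load_fits,
    predictions_frame,
    save_fits,
    targets_frame,
)

from conftest import make_series


def planted_dataset(seed, n=180, r2=0.95):
    """Amplitude/phase-style features with g_max a linear function of two
    amplitudes plus Gaussian noise calibrated to the requested R^2."""
    rng = np.random.default_rng(seed)
    cols = {}
    for j in range(5):
        cols[f"amp_k{j + 1}"] = rng.gamma(4.0, 5.0, n)
        cols[f"phase_k{j + 1}"] = rng.uniform(-np.pi, np.pi, n)
    X = pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])
    signal = 2.0 * X["amp_k1"] + 1.5 * X["amp_k3"]
    noise_sd = np.sqrt(signal.var() * (1 - r2) / r2)
    y = 200.0 + signal + rng.normal(0, noise_sd, n)
    targets = pd.DataFrame({"g_max": y}, index=X.index)
    return X, targets


class TestExtractEventTargets:
    def test_unique_extremes_and_times(self):
        vals = np.full(2 * SLOTS_PER_DAY, 100.0)
        vals[340] = 250.0
        vals[100] = 60.0
        t = extract_event_targets(make_series(vals, n_days=2))
        assert t.g_max == 250.0 and t.g_min == 60.0
        assert t.t_max == pytest.approx(340 * 5 / 60)
        assert t.t_min == pytest.approx(100 * 5 / 60)
        assert t.log_t_max == pytest.approx(np.log(t.t_max))

    def test_constant_series_flagged_degenerate(self):
        t = extract_event_targets(make_series(np.full(SLOTS_PER_DAY, 100.0), n_days=1))
        assert t.degenerate

    def test_tied_maxima_take_first_occurrence(self):
        vals = np.full(SLOTS_PER_DAY, 100.0)
        vals[50] = vals[200] = 250.0
        t = extract_event_targets(make_series(vals, n_days=1))
        assert t.t_max == pytest.approx(50 * 5 / 60)

    def test_times_can_exceed_24_hours(self):
        vals = np.full(2 * SLOTS_PER_DAY, 100.0)
        vals[SLOTS_PER_DAY + 51] = 300.0  # 04:15 on day 2 -> 28.25 h
        t = extract_event_targets(make_series(vals, n_days=2))
        assert t.t_max == pytest.approx(28.25)

    def test_exp_log_round_trip(self):
        vals = np.full(SLOTS_PER_DAY, 100.0)
        vals[77] = 250.0
        vals[120] = 55.0
        t = extract_event_targets(make_series(vals, n_days=1))
        assert np.exp(t.log_t_max) == pytest.approx(t.t_max)
        assert np.exp(t.log_t_min) == pytest.approx(t.t_min)


class TestBuildFeatureMatrix:
    def test_columns_follow_selected_frequencies(self, sinusoid_factory):
        decs = [
            decompose(sinusoid_factory(period_days=3.0, amplitude=25.0, n_days=6,
                                       subject_id=f"s{i}"))
            for i in range(4)
        ]
        X = build_feature_matrix(decs, min_select_frac=0.5)
        assert "amp_k2" in X.columns and "phase_k2" in X.columns
        assert len(X) == 4

    def test_rows_aligned_by_subject_id(self, sinusoid_factory):
        decs = [
            decompose(sinusoid_factory(period_days=2.0, amplitude=20.0, n_days=6,
                                       subject_id=sid))
            for sid in ("b", "a")
        ]
        X = build_feature_matrix(decs, k_set=[3])
        assert list(X.index) == ["a", "b"]
        assert not X.isna().any().any()


class TestFitPredictiveModel:
    def test_planted_predictors_recovered(self):
        X, targets = planted_dataset(seed=0)
        fit = fit_predictive_model(X, targets, responses=("g_max",), seed=0)["g_max"]
        assert sorted(fit.predictors) == ["amp_k1", "amp_k3"]
        assert fit.r_squared == pytest.approx(0.95, abs=0.05)

    def test_deterministic_given_seed(self):
        X, targets = planted_dataset(seed=1)
        a = fit_predictive_model(X, targets, responses=("g_max",), seed=7)["g_max"]
        b = fit_predictive_model(X, targets, responses=("g_max",), seed=7)["g_max"]
        assert a.predictors == b.predictors
        assert a.coefficients == b.coefficients
        assert a.excluded_subjects == b.excluded_subjects

    def test_subsample_larger_than_cohort_rejected(self):
        X, targets = planted_dataset(seed=2, n=50)
        with pytest.raises(ParameterError, match="fraction"):
            fit_predictive_model(X, targets, responses=("g_max",), n_subsample=140)

    def test_small_cohort_uses_fractional_subsample(self):
        X, targets = planted_dataset(seed=3, n=40)
        fit = fit_predictive_model(X, targets, responses=("g_max",), seed=0)["g_max"]
        assert fit.n_subsample == 32  # 0.8 of 40

    def test_collinear_column_dropped(self):
        X, targets = planted_dataset(seed=4)
        X["dup"] = 2.0 * X["amp_k1"]
        fit = fit_predictive_model(X, targets, responses=("g_max",), seed=0)["g_max"]
        assert "dup" not in fit.predictors or "amp_k1" not in fit.predictors

    def test_r2_not_hurt_by_extra_true_feature_noiseless(self):
        # noiseless planted response: adding the second true feature to the
        # candidate set can only improve fit
        rng = np.random.default_rng(5)
        n = 120
        X = pd.DataFrame({
            "amp_k1": rng.gamma(4, 5, n),
            "amp_k2": rng.gamma(4, 5, n),
            "amp_k3": rng.gamma(4, 5, n),
        }, index=[f"S{i}" for i in range(n)])
        y = 100 + 2 * X["amp_k1"] + 3 * X["amp_k2"]
        t = pd.DataFrame({"g_max": y}, index=X.index)
        small = fit_predictive_model(X[["amp_k1", "amp_k3"]], t,
                                     responses=("g_max",), seed=0)["g_max"]
        full = fit_predictive_model(X, t, responses=("g_max",), seed=0)["g_max"]
        assert full.r_squared >= small.r_squared
        assert full.r_squared == pytest.approx(1.0)


class TestPredictEvents:
    def test_intercept_only_predicts_constant(self):
        fit = ModelFit(
            response="g_max", predictors=[], coefficients={"const": 150.0},
            feature_means={}, feature_sds={}, r_squared=0.0, f_stat=np.nan,
            df_model=0, df_resid=10, f_pvalue=np.nan, shapiro_w=np.nan,
            shapiro_p=np.nan, residuals={}, excluded_subjects=[],
            n_subsample=10, n_repeats=1, alpha=0.05, seed=0,
        )
        X = pd.DataFrame({"amp_k1": [1.0, 2.0]}, index=["a", "b"])
        preds = predict_events({"g_max": fit}, X)
        assert all(p.g_max == 150.0 for p in preds)

    def test_log_time_back_transform(self):
        fit = ModelFit(
            response="log_t_max", predictors=[],
            coefficients={"const": float(np.log(12.0))},
            feature_means={}, feature_sds={}, r_squared=0.0, f_stat=np.nan,
            df_model=0, df_resid=10, f_pvalue=np.nan, shapiro_w=np.nan,
            shapiro_p=np.nan, residuals={}, excluded_subjects=[],
            n_subsample=10, n_repeats=1, alpha=0.05, seed=0,
        )
        X = pd.DataFrame({"amp_k1": [1.0]}, index=["a"])
        preds = predict_events({"log_t_max": fit}, X)
        assert preds[0].t_max == pytest.approx(12.0)

    def test_in_sample_error_bounded_in_low_noise_regime(self):
        X, targets = planted_dataset(seed=6, r2=0.99)
        fits = fit_predictive_model(X, targets, responses=("g_max",), seed=0)
        preds = predictions_frame(predict_events(fits, X))
        keep = targets.index.difference(fits["g_max"].excluded_subjects)
        resid_sd = np.std(list(fits["g_max"].residuals.values()))
        err = np.abs(preds.loc[keep, "g_max"] - targets.loc[keep, "g_max"])
        assert np.quantile(err, 0.95) < 2.5 * resid_sd + 1e-9

    def test_missing_predictor_column_named(self):
        X, targets = planted_dataset(seed=7)
        fits = fit_predictive_model(X, targets, responses=("g_max",), seed=0)
        bad = X.drop(columns=["amp_k1"])
        with pytest.raises(KeyError, match="amp_k1"):
            predict_events(fits, bad)


class TestEvaluateAndSerialize:
    def test_perfect_linear_data_r2_one(self):
        rng = np.random.default_rng(8)
        n = 60
        X = pd.DataFrame({"amp_k1": rng.gamma(4, 5, n)},
                         index=[f"S{i}" for i in range(n)])
        y = 50.0 + 3.0 * X["amp_k1"]
        t = pd.DataFrame({"g_max": y}, index=X.index)
        fits = fit_predictive_model(X, t, responses=("g_max",), seed=0)
        diag = evaluate_fit(fits["g_max"], t, X)
        assert diag["r_squared"] == pytest.approx(1.0)

    def test_fits_round_trip_through_json(self, tmp_path):
        X, targets = planted_dataset(seed=9)
        fits = fit_predictive_model(X, targets, responses=("g_max",), seed=0)
        save_fits(fits, tmp_path / "m.json")
        back = load_fits(tmp_path / "m.json")
        assert back["g_max"].predictors == fits["g_max"].predictors
        assert back["g_max"].coefficients == fits["g_max"].coefficients

    def test_targets_frame_drops_degenerate(self):
        t1 = extract_event_targets(make_series(np.full(SLOTS_PER_DAY, 100.0), n_days=1))
        vals = np.full(SLOTS_PER_DAY, 100.0)
        vals[3] = 200.0
        t2 = extract_event_targets(make_series(vals, subject_id="ok", n_days=1))
        df = targets_frame([t1, t2])
        assert list(df.index) == ["ok"]
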