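"""FFT decomposition, Parseval accounting, gap filling, period binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from glycoscope import (
    SubjectRecord,
    bin_max_period,
    cohort_oscillation,
    decompose,
    gap_fill,
    reconstruct,
)
from glycoscope.cgm_core import SLOTS_PER_DAY
from glycoscope.spectral import GapsPresentError, PERIOD_BIN_LABELS

from conftest import make_series


class TestDecompose:
    def test_three_day_sinusoid_dominates(self, sinusoid_factory):
        d = decompose(sinusoid_factory(period_days=3.0, amplitude=25.0, n_days=6))
        assert d.max_period_days == pytest.approx(3.0)
        # single dominant peak: k=2 carries essentially all power
        assert d.psd[2] / d.total_power > 0.999

    def test_constant_series_has_zero_power(self, series_factory):
        d = decompose(series_factory(np.full(6 * SLOTS_PER_DAY, 150.0), n_days=6))
        assert d.total_power == pytest.approx(0.0, abs=1e-12)
        assert not d.selected.any()

    def test_two_sinusoids_both_selected_and_circadian_flagged(self, series_factory):
        n = 6 * SLOTS_PER_DAY
        t_days = np.arange(n) / SLOTS_PER_DAY
        vals = (150.0 + 20.0 * np.sin(2 * np.pi * t_days)           # 24-h cycle
                + 20.0 * np.sin(2 * np.pi * t_days / 3.0))          # 3-day cycle
        d = decompose(series_factory(vals, n_days=6), threshold_au=1000.0)
        assert d.circadian_flag
        assert d.selected[2] and d.selected[6]  # k=2 (3 d), k=6 (1 d)
        assert d.selected.sum() == 2

    def test_gaps_rejected_with_guidance(self, series_factory):
        gaps = np.zeros(2 * SLOTS_PER_DAY, dtype=bool)
        gaps[3] = True
        s = series_factory(np.full(2 * SLOTS_PER_DAY, 100.0), gap_mask=gaps, n_days=2)
        with pytest.raises(GapsPresentError, match="gap_fill"):
            decompose(s)

    def test_quantile_threshold_mode(self, sinusoid_factory):
        d = decompose(sinusoid_factory(period_days=2.0, amplitude=30.0, n_days=6),
                      threshold_mode="quantile", quantile=0.999)
        assert d.selected[3]  # k=3 is the 2-day line

    def test_parseval_energy_balance(self, series_factory):
        rng = np.random.default_rng(5)
        vals = 150.0 + rng.normal(0, 20, 6 * SLOTS_PER_DAY)
        s = series_factory(np.clip(vals, 41, None), n_days=6)
        d = decompose(s)
        x = s.values - s.values.mean()
        energy = float((x**2).sum())
        assert d.total_power + d.psd[0] == pytest.approx(energy, rel=1e-10)


class TestReconstruct:
    def test_full_reconstruction_is_identity(self, series_factory):
        rng = np.random.default_rng(6)
        vals = np.clip(140 + rng.normal(0, 25, 4 * SLOTS_PER_DAY), 41, None)
        s = series_factory(vals, n_days=4)
        d = decompose(s)
        err = np.max(np.abs(reconstruct(d, add_mean=True) - s.values))
        assert err < 1e-8

    def test_band_limited_single_sinusoid_exact(self, sinusoid_factory):
        s = sinusoid_factory(period_days=3.0, amplitude=25.0, n_days=6)
        d = decompose(s, threshold_au=100.0)
        rec = reconstruct(d, only_selected=True, add_mean=True)
        np.testing.assert_allclose(rec, s.values, atol=1e-8)

    def test_band_limited_variance_never_exceeds_signal(self, series_factory):
        rng = np.random.default_rng(7)
        vals = np.clip(150 + 20 * np.sin(np.arange(6 * SLOTS_PER_DAY) / 40.0)
                       + rng.normal(0, 15, 6 * SLOTS_PER_DAY), 41, None)
        s = series_factory(vals, n_days=6)
        d = decompose(s, threshold_mode="quantile", quantile=0.99)
        rec = reconstruct(d, only_selected=True)
        assert rec.var() <= s.values.var() + 1e-9


class TestGapFill:
    def test_gap_free_input_returned_identical(self, sinusoid_factory):
        s = sinusoid_factory(period_days=2.0, amplitude=20.0, n_days=6)
        out = gap_fill(s)
        np.testing.assert_array_equal(out.values, s.values)

    def test_observed_samples_bit_exact(self, sinusoid_factory):
        s = sinusoid_factory(period_days=3.0, amplitude=25.0, n_days=6)
        rng = np.random.default_rng(8)
        gaps = rng.random(s.n_slots) < 0.05
        gappy = make_series(s.values.copy(), gap_mask=gaps, n_days=6)
        out = gap_fill(gappy)
        np.testing.assert_array_equal(out.values[~gaps], s.values[~gaps])
        assert not out.gap_mask.any()

    def test_planted_sinusoid_recovered_in_gaps(self, sinusoid_factory):
        s = sinusoid_factory(period_days=3.0, amplitude=25.0, n_days=6)
        rng = np.random.default_rng(9)
        gaps = rng.random(s.n_slots) < 0.05
        out = gap_fill(make_series(s.values.copy(), gap_mask=gaps, n_days=6))
        rmse = np.sqrt(np.mean((out.values[gaps] - s.values[gaps]) ** 2))
        assert rmse < 0.05 * 25.0

    def test_constant_series_hour_gap_filled_with_constant(self, series_factory):
        vals = np.full(2 * SLOTS_PER_DAY, 123.0)
        gaps = np.zeros(2 * SLOTS_PER_DAY, dtype=bool)
        gaps[100:112] = True
        out = gap_fill(series_factory(vals, gap_mask=gaps, n_days=2))
        np.testing.assert_allclose(out.values, 123.0, atol=1e-6)

    def test_excessive_gap_fraction_rejected(self, series_factory):
        vals = np.full(2 * SLOTS_PER_DAY, 100.0)
        gaps = np.zeros(2 * SLOTS_PER_DAY, dtype=bool)
        gaps[: int(0.6 * len(gaps))] = True
        with pytest.raises(ValueError, match="missing"):
            gap_fill(series_factory(vals, gap_mask=gaps, n_days=2))

    def test_error_shrinks_with_gap_fraction_on_average(self):
        # band-limited signal: mean fill error decreases as gaps become rare
        n_days = 4
        n = n_days * SLOTS_PER_DAY
        t_days = np.arange(n) / SLOTS_PER_DAY
        truth = 120.0 + 20.0 * np.sin(2 * np.pi * t_days / 2.0)
        mean_err = {}
        for frac in (0.2, 0.02):
            errs = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                gaps = rng.random(n) < frac
                gaps[0] = gaps[-1] = False
                out = gap_fill(make_series(truth.copy(), gap_mask=gaps, n_days=n_days))
                errs.append(np.sqrt(np.mean((out.values[gaps] - truth[gaps]) ** 2)))
            mean_err[frac] = np.mean(errs)
        assert mean_err[0.02] <= mean_err[0.2]
        assert mean_err[0.02] < 0.02 * 20.0  # < 2% of amplitude


class TestBinMaxPeriod:
    @pytest.mark.parametrize(
        "period,label",
        [
            (2.5, "> 2 to < 3"),
            (7.0, "> 6"),
            (3.0, "> 3 to < 4"),   # half-open lower boundary
            (1.5, "<2"),
            (5.99, "> 5 to < 6"),
            (6.0, "> 6"),
        ],
    )
    def test_boundary_rule(self, period, label):
        assert bin_max_period(period) == label

    def test_bins_partition_positive_axis(self):
        for period in np.linspace(0.1, 12.0, 333):
            assert bin_max_period(float(period)) in PERIOD_BIN_LABELS

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bin_max_period(0.0)


class TestCohortOscillation:
    def _dec(self, sid, period, power=1000.0, circadian=False):
        from glycoscope.spectral import SpectralDecomposition

        return SpectralDecomposition(
            subject_id=sid, n=1728, n_days=6.0, mean=150.0,
            freq_cpd=np.arange(865) / 6.0, coeffs=np.zeros(865, dtype=complex),
            psd=np.zeros(865), selected=np.zeros(865, dtype=bool),
            total_power=power, max_period_days=period,
            circadian_flag=circadian, threshold_au=15000.0,
        )

    def test_uniform_bin_prevalence(self):
        decs = [self._dec(f"s{i}", 2.5) for i in range(10)]
        recs = [SubjectRecord(f"s{i}", "T1D", "male", 30.0) for i in range(10)]
        prev, power = cohort_oscillation(decs, recs)
        assert prev.loc[("T1D", "male"), "> 2 to < 3"] == pytest.approx(100.0)
        assert power.loc[("T1D", "male"), "total_power_mean"] == pytest.approx(1000.0)

    def test_planted_periods_recovered_noiseless(self, sinusoid_factory):
        periods = [2.0, 3.0, 6.0]
        decs, recs = [], []
        for i, p in enumerate(periods):
            s = sinusoid_factory(period_days=p, amplitude=25.0, n_days=6,
                                 subject_id=f"s{i}")
            decs.append(decompose(s))
            recs.append(SubjectRecord(f"s{i}", "control", "female", 40.0))
        for d, p in zip(decs, periods):
            assert d.max_period_days == pytest.approx(p)
        prev, _ = cohort_oscillation(decs, recs)
        row = prev.loc[("control", "female")]
        assert row["> 2 to < 3"] == pytest.approx(100 / 3)
        assert row["> 3 to < 4"] == pytest.approx(100 / 3)
        assert row["> 6"] == pytest.approx(100 / 3)

    def test_t1d_total_power_exceeds_control_on_default_cohort(self):
        from glycoscope import CohortSpec, simulate_cohort

        spec = CohortSpec(n_control_female=6, n_control_male=6,
                          n_t1d_female=6, n_t1d_male=6, master_seed=4)
        decs, recs = [], []
        for s in simulate_cohort(spec):
            decs.append(decompose(gap_fill(s.series)))
            recs.append(s.record)
        _, power = cohort_oscillation(decs, recs)
        t1d = power.loc[("T1D",), "total_power_mean"].mean()
        ctrl = power.loc[("control",), "total_power_mean"].mean()
        assert t1d > ctrl
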