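# Methods

## Data model

A recording is a regular 5-minute grid (288 slots/day, 1728 over the
default 6-day window) anchored at the first sample's timestamp floored to a
5-minute boundary. Raw CSV rows are sorted, snapped to the grid, duplicate
timestamps averaged, and empty slots flagged in an explicit gap mask.
Recordings with more than 50% of slots missing are rejected as
unanalyzable. Missing samples are excluded from all descriptive metrics and
are only ever reconstructed — explicitly, by the spectral gap filler — for
the analyses that require a contiguous signal (unit-root testing, FFT,
event extraction). Hourly aggregation averages each clock hour's observed
samples; an hour with no observations is missing, never zero. Clock phases
follow the day = 08:00–20:00 / night = 20:00–08:00 convention, the night
window belonging to the day on which it opens; local clock time is used
with no daylight-saving handling, since phase boundaries are defined as
clock hours.

## Synthetic cohort generator

Each subject's trace is the sum of

- a baseline level (mg/dL),
- a circadian sinusoid (24-h period, subject-specific phase),
- one or two infradian sinusoids with periods of 2–6 days,
- meal excursions at breakfast/lunch/dinner (instantaneous rise of
  amplitude ~uniform ±30% around the subject's meal amplitude, exponential
  decay with a 90-min time constant),
- AR(1) sensor noise on the 5-min grid with stationary SD `noise_sd` and
  lag-1 autocorrelation `noise_ar1` (CGM noise is strongly autocorrelated;
  AR(1) is the minimal such model),
- optionally a Gaussian random walk (`drift_sd` mg/dL per step) — the
  non-stationary regime: the process contains a unit root exactly when
  `drift_sd > 0`, and is covariance-stationary otherwise,

floored at 40 mg/dL for physiological plausibility. A profile forcing more
than 10% of samples onto the floor is rejected as degenerate; the cohort
generator retries such a draw up to 8 times with a fresh noise seed before
propagating the error. Sensor dropouts are geometric runs (mean 30 min)
covering a target fraction of slots, with at least one observed sample kept
per day. Every subject's seed derives from the master seed through a
`SeedSequence` child, so cohorts are bit-reproducible and subjects
individually reproducible.

Group defaults encode a T1D-vs-control contrast: baseline 170 ± 20 vs
95 ± 8 mg/dL, noise SD 22 ± 6 vs 7 ± 2, circadian amplitude 20 ± 6 vs
8 ± 3, meal amplitude 55 ± 15 vs 30 ± 8, infradian amplitude 30 ± 8 vs
5 ± 2 mg/dL, non-stationary fraction 10% vs 25%. No quantitative amplitudes
for multi-day glycemic oscillations are established in the literature;
these are free parameters chosen once so that (a) T1D mean/SD/HbA1c and
total oscillation power exceed control, and (b) the dominant oscillation of
a typical T1D subject is infradian (2–6 days) rather than the 1-day
meal/circadian line. The generator records each subject's true dominant
infradian period and stationarity regime as ground truth for recovery
tests.

What the generator does **not** emulate: sensor calibration drift and
nonlinearity, glucose–insulin feedback dynamics, exercise and hormonal
effects, non-Gaussian noise bursts, or day-to-day meal-time variability.
Passing recovery tests therefore demonstrate correctness of the analysis
chain under the assumed signal structure, not clinical validity on real
recordings.

## Glycemic metrics

Mean, SD and CV = SD/mean are computed over all observed samples of the
full record; SD uses the sample (n−1) convention (configurable `ddof`).
Estimated HbA1c uses the affine maps `HbA1c% = (mean + 46.7)/28.7` and
`mmol/mol = 10.93·% − 23.5`. Time-in-range cut-offs are strict — above 180
mg/dL counts hyperglycemic, below 70 hypoglycemic, boundary values
euglycemic — and the three percentages sum to 100 over observed samples.
70 mg/dL is the standard clinical hypoglycemia boundary; both cut-offs are
arguments. Phase magnitudes are the mean of above-range samples
(hyperglycemia magnitude) and of in-range samples (euglycemia magnitude)
per phase; an empty category is reported as absent (`None`), never as 0.

## Stationarity (Dickey–Fuller)

The AR(1) model `y_t = ρ·y_{t−1} + u_t` is fitted in first-difference form
`Δy_t = (ρ−1)·y_{t−1} + u_t`, with τ = (ρ̂−1)/se(ρ̂). Two variants: the
bare regression (`pure_AR1`, matching the model as written, appropriate for
zero-mean signals) and `with_intercept`, which demeans and is the correctly
calibrated choice for glucose, whose mean is far from zero; the pipeline
default is `with_intercept`. No augmentation lags are used.

τ does not follow a t distribution under the unit-root null, so p-values
are left-tail empirical quantiles of a seeded Monte-Carlo null: 10,000
simulated driftless random walks of the observed length per (length,
variant) pair, cached, with a +1/(N+1) continuity correction. The simulated
5% quantiles reproduce the tabulated Dickey–Fuller critical values (≈ −1.94
without constant, ≈ −2.87 with constant). Rejection of the unit root at
α = 0.05 labels the signal *stationary* (deterministic oscillation);
failure to reject labels it *non-stationary*. Constant input is a
degenerate error; at least 20 contiguous observations are required, and
gapped series must be gap-filled first.

A caveat established by simulation: when a random walk is buried in
stationary noise whose innovations are much larger than the walk's (e.g.
drift 2–3 mg/dL/step under AR(1) noise of SD 22), the test at 5-minute
resolution almost never detects the unit root — the attenuation acts like
errors-in-variables. Hourly averaging (24 points/day, noise averaged down
by √12) markedly improves detection and the test accepts hourly series
directly; prevalence studies on noisy cohorts should prefer it.

## Spectral analysis

The FFT is taken on the mean-removed signal. The one-sided PSD is
`psd_k = w_k·|X_k|²/N` (w = 2 except at DC and Nyquist), so that
`Σ psd_k` equals the time-domain energy `Σ x²` of the mean-removed signal
(Parseval); total power is the sum over nonzero frequencies. Frequencies
with PSD above an absolute threshold (default 15,000 a.u. under this
normalization) are *selected*; since any absolute threshold is meaningful
only relative to a normalization convention, a quantile mode (top 1%
default) is provided. The dominant period is `n_days/k*` for the
nonzero-frequency PSD argmax; prevalence bins are half-open
[2,3), [3,4), [4,5), [5,6), [6,∞) days labelled "> 2 to < 3" … "> 6", plus
"<2" for sub-2-day dominance (a dominant 1-day line is possible and must be
representable). Half-open boundaries make on-grid ties (e.g. exactly 3.0
days on a 6-day record) deterministic. A subject is circadian when a
selected frequency lies within one grid step (1/n_days cycles/day) of
1 cycle/day.

Gap filling is Papoulis–Gerchberg alternating projection: initialize gaps
by linear interpolation, then iterate FFT → retain the K strongest nonzero
frequencies → iFFT → restore observed samples, until successive gap fills
move < 1e−3 mg/dL (or 200 iterations). K starts at 4 and doubles until the
band-limited projection reproduces the observed samples within 5% of their
SD — the smallest spectral support consistent with the observations, i.e. a
minimum-energy oscillation reconstruction. Observed samples are returned
bit-exactly; gap-free input is returned unchanged. On a planted 3-day
sinusoid with 5% random gaps the filled-slot RMSE is ≈ 0.3% of the
amplitude (50-seed simulation in the test suite).

## Predictive model

Targets per subject: global maximum/minimum glycemia of the gap-filled
trace and their first-occurrence times in continuous hours from midnight of
recording day 1 (a maximum at 04:13 of day 2 is t = 28.2 h); times are
log-transformed for fitting and exponentiated for prediction. A slot-0
extreme at a midnight-anchored recording would give t = 0; it is clamped to
one grid step so the log exists. Features are the Fourier weights —
amplitude 2|X_k|/N and phase per frequency — for frequencies selected in at
least 25% of subjects (configurable, or an explicit harmonic set), capped
for small cohorts at the strongest cohort-mean-PSD frequencies so the
design stays full rank.

Per response, with features z-scored on the full cohort:

1. 40 random subsamples of 140 subjects each (for cohorts under 150
   subjects the subsample is 80% of the cohort) are fitted by OLS on the
   full candidate set;
2. subjects with internally studentized residual |r| > 3 in more than one
   subsample fit are excluded as unstable points (the threshold and rule
   mirror repeated-adjustment screening; the excluded count is an outcome,
   not a constant);
3. backward stepwise elimination minimizing AIC from the full model;
4. sequential pruning of predictors with p ≥ 0.05 (worst first, refitting);
5. report: standardized coefficients, R², F and degrees of freedom,
   Shapiro–Wilk W/p of residuals, exclusions, and the seed.

Everything is reproducible from (data, seed); collinear or constant columns
are dropped with a logged warning. Predicted maxima below predicted minima
are flagged, never reordered.

Known property, quantified by simulation: stepwise selection does not
control the family-wise error of the retained set. With 10 null candidates
and n = 180, the final model retains ≥ 1 spurious predictor in roughly half
of seeds (the maximum of ~10 null t-statistics exceeds the 5% cut ~40% of
the time). Planted-signal recovery is nevertheless reliable: with two true
amplitude predictors at theoretical R² = 0.95 the procedure recovers
exactly the planted set and the R² in the reference run. Users needing a
conservative retained set should lower α or apply their own multiplicity
correction; the default mirrors the per-coefficient 0.05 rule.

## Pipeline and problem sizes

`run_pipeline` executes: cohort input → raw-grid metrics → gap filling →
Dickey–Fuller → FFT decomposition → event extraction + feature matrix →
predictive model → report (JSON + Markdown), with every stage writing its
CSV artifact and all randomness derived from one master seed; reruns are
byte-identical. Between-group annotations (two-way group × sex ANOVA,
Mann–Whitney) are delegated to statsmodels/scipy and skipped with a logged
note for strata below 2 subjects. The default synthetic configuration is 5
subjects per group × sex cell (20 total, 6 days each); the reproduction
script uses 15 per cell (60 subjects), and the validation simulations use
25–200 replicates per claim — sizes chosen so each claim's Monte-Carlo
error is small relative to the asserted margin.

## Limitations

- The predictive model interpolates within the recorded window; it does not
  extrapolate beyond it, and time predictions inherit the log-scale
  error structure (multiplicative on the hour scale).
- The absolute PSD selection threshold is convention-bound; cross-study
  comparisons should use the quantile mode.
- Unit-root detection at 5-minute resolution is weak against drifts small
  relative to sensor noise (see above); stationarity prevalences on noisy
  cohorts are conservative (biased toward "stationary").
- The generator's meal schedule is fixed and its components additive; real
  postprandial dynamics are state-dependent.
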