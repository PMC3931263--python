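# Methods

This note documents the models, conventions, parameters and numerical
choices behind patchkit, and what the synthetic validation data do and do
not establish about behavior on real recordings.

## Data model and conventions

A sweep is a uniformly sampled trace: sample *i* lies at t0 + i·dt, with
time in ms and signal in mV (voltage) or pA (current).  Cursor regions are
half-open 0-based sample windows [begin, end); cursor positions given in ms
on the command line are converted by rounding half-up, and the conversion
is logged.  All sweeps in a channel share dt and unit.  Baseline SD is the
population SD (it is a noise estimate over the cursor window, not an
inference about a larger population).

The low-pass filter is a zero-phase Gaussian kernel parameterized by its
−3 dB frequency f_c, σ_t = √(ln 2)/(2π·f_c).  Zero phase was chosen so
that filtering never shifts measured latencies; the same kernel (applied
in the frequency domain) regularizes the deconvolution detector, and the
same σ_t shapes the colored noise of the EPSC generator.

## Principal measurements

* **Peak** — extremum of the n-point moving average (n odd) of the
  baseline-subtracted trace within the peak region; direction `up`,
  `down`, or `both` (largest magnitude; ties go to the earlier index).
  When n > 1, the reported *value* is the moving-average extremum while
  the *index* is refined to the raw extremum inside the smoothing window,
  so rise/decay searches start from the actual peak sample.
* **Fraction crossings** (rise time, half duration) — located by linear
  interpolation between the bracketing samples and searched *backward*
  from the peak (the last crossing before the peak).  Interpolation is
  needed to reach one-sampling-point accuracy at ordinary rates; the
  backward search makes the crossing robust to noise before event onset.
* **Slopes** — fixed-interval differences (y(t+w)−y(t))/w with
  w = max(1, round(0.05 ms/dt)) samples, i.e. the number of samples closest
  to 50 µs; at sampling intervals of 50 µs or coarser this degrades to the
  adjacent-sample difference.  The window trades a small deterministic
  chord bias (≈(θ²/6) relative, θ = π·f_signal·w·dt) for a large variance
  reduction under noise; see the validation section.
* **Foot** — extrapolated onset t_low − [f_low/(f_high−f_low)]·(t_high−t_low)
  from the 20%/80% crossings.  The synaptic latency default is presynaptic
  maximal rising slope → postsynaptic foot.

## Model fitting

Optimization is MINPACK Levenberg–Marquardt (`scipy.optimize.least_squares`,
`method="lm"`), capped at 2048 function evaluations with 10⁻⁸ relative
stopping tolerances.  Fit times are taken relative to the region start.
With rescaling enabled (the default) the residuals are divided by the data
range, so the optimizer effectively works on the [0,1]-normalized trace;
parameters remain in natural units throughout, which keeps the
back-transform exact.  A fit is successful when the normalized SSE is
≤ 0.001 — one scale-free threshold across models of different units.

Initial estimates per model (the measurement-seeding strategy):

| model | seeding |
|---|---|
| monoexp / biexp | offset from the tail mean; τ (and amplitude) from linear regression of ln(y−C) on t over samples above 5% of the peak; the bi-exponential peels the slow component from the second half first |
| alpha synapse | τ = time-to-peak, A = peak value (exact on clean data, since the model peaks at t=τ with value A) |
| gaussian | μ = peak time, σ = FWHM/(2√(2 ln 2)), A = peak value; if the half level is not crossed inside the region (pulse clipped by an edge) σ falls back to one sixth of the region span |
| delayed biexp | δ = foot time, τ₂ from log-linear decay, τ₁ = (20–80% rise)/1.4 |
| two-gated Na⁺ | τ_m = 20–80% rise, τ_h from log-linear decay |
| HH Na⁺ (m³h) | τ_m = (20–80% rise)/1.4, τ_h from log-linear decay |

For the gated/delayed kernels the amplitude seed divides the measured peak
by the closed-form unit-amplitude kernel maximum
(u = τ_m/(τ_m + p·τ_h), peak = (1−u)^p·u^(τ_m/τ_h)).  The seeding context
takes its baseline from the first region sample: these event models start
at baseline at the left cursor, and a longer baseline window would swallow
rising phases faster than ~1% of the region span.

**Convergence grids.**  `validate_fit_grid` draws parameters as
reference × N(1, cv) per parameter (redrawn until positive and inside the
model bounds; cv defaults to 0.3, matching the time-constant variability
used by the EPSC generator), evaluates the model noise-free over an
adaptive window that comfortably contains the event (e.g. 12τ for the
alpha synapse, μ+6σ for the Gaussian; 1000 samples), fits with the chosen
seeding, and reports the percentage of unsuccessful fits.  Reference
values — alpha (A=1, τ=5 ms); monoexp (A=1, τ=10 ms); delayed biexp (A=1,
τ₁=1, τ₂=10, δ=1 ms); gated models (A=1, τ_m=0.5, τ_h=3 ms); Gaussian
(A=1, μ=10, σ=2 ms) — are physiologically plausible PSC/AP-conductance
scales.  With measurement seeding all models converge on 100% of grids at
cv 0.3 (and remain ≥99% out to cv 0.8); seeding every fit from the grid's
mean parameter vector instead degrades markedly on wide grids (e.g. the
Gaussian at cv 0.8), which is why measurement seeding is the default.

## Event detection

The template is bootstrapped from the recording itself: excursions beyond
baseline ± 5 SD are peak-aligned (candidates closer than one window span
are merged), averaged over a [−1 ms, +10 ms] window, fitted with the
delayed bi-exponential event model, and the fitted curve is normalized to
unit extremum.  The sliding straight-line fit runs on cumulative sums plus
one FFT cross-correlation (O(N) amortized per position); positions whose
window would overrun the trace end are marked invalid rather than padded.
The correlation criterion is |r(p, y)| — the correlation between the
*optimally scaled* template and the data, which is non-negative and peaks
at 1 for matching events of either polarity.  The scale criterion is
m/√(χ²_min/(n−1)), the scale factor in units of the local noise SD.

Deconvolution divides the trace spectrum by the zero-padded template
spectrum (magnitudes floored at 10⁻⁶ of the spectral maximum, phase kept)
and applies the Gaussian low-pass at f_c = 1 kHz — matching the passband
of the colored noise it is meant to suppress.  The noise SD of a criterion
trace is the σ of a Gaussian fitted to its all-point histogram
(Freedman–Diaconis bins, fit restricted to ±2 IQR around the mode so event
tails do not inflate it; the fit reuses the package's own Gaussian model
machinery).  This estimate is accurate to ~1% on clean Gaussian data and
within 10% under 1% gross outlier contamination.

**Thresholds.**  Detection thresholds are multiples of that SD.  The
deconvolution default is 4 SD, in the typical 4.0–4.5 range for this
detector.  For template matching the package default is 5 SD, set by
minimizing the total number of false positives plus false negatives on the
reference synthetic train.  A lower multiple (2–3 SD) is usable for short
stretches of data but not for minute-scale recordings: the template
criteria are scale-invariant, so their noise distribution is fixed, and at
2.5 SD a 60 s, 20 kHz recording contains hundreds of suprathreshold noise
excursions regardless of how clean the data are.  Runs closer than the
template rise time (the default minimum interval) are merged keeping the
larger criterion peak; the event onset is the criterion extremum of the
run, and the event peak is that index plus the template's peak latency.
Detections are benchmarked against generator truth by greedy nearest
matching within 2 ms (ties to the earlier truth).

## Synthetic data

* **Analytic families** — exact evaluation of A·sin(2πfx), A·e^(−t/τ)+C
  and Gaussian pulses; the randomized harness multiplies reference
  parameters by N(1, 0.3).  Expected values: sine peak A, 20–80% rise
  (arcsin 0.8 − arcsin 0.2)/2πf, half width 2(arcsin 1 − arcsin 0.5)/2πf,
  maximal slopes ±2πfA.  Slopes are validated with the adjacent-sample
  window: the 50 µs window's deterministic chord bias (≈0.4% at 10⁴
  samples/period) exceeds the one-sampling-point tolerance by design, and
  that window exists for noisy data, not for noise-free analytic traces.
  The threshold crossing is validated on the *time-reversed* exponential
  decay (an exponential rise whose slope increases monotonically, giving
  the closed-form crossing t* = T + τ·ln(Rτ/A)); on the decay itself the
  first crossing is degenerate at t = 0.  The Gaussian-family baseline is
  checked against the erf integral over the sampled window extended half a
  step per side (midpoint rule, exact to O(dt²) for any window placement).
* **Action potential** — a single-compartment Wang–Buzsáki interneuron
  (C_m = 1 µF/cm², g_L = 0.1, g_Na = 35, g_K = 9 mS/cm², φ = 5, sodium
  activation at steady state), integrated with fixed-step RK4.  The
  compartment area defaults to 10⁻⁴ cm² so the 100 pA step is 1 µA/cm²,
  which drives repetitive firing; the packaged reference waveform is a
  5 ms window around the *second* spike of a 100 ms, 400 kHz simulation
  (the first spike carries the stimulus-onset transient).  Its maximal
  rising slope is ≈435 V/s.  Step-halving changes the maximal slope by
  <0.1%.  Absolute slope values depend on the chosen area, so the noise
  benchmarks below are stated as estimator *properties*, not as absolute
  references.
* **Noise and quantization** — white Gaussian thermal noise with
  σ = √(4k_B·T·B·Z) (T = 298 K; B the Nyquist frequency of the target
  rate; Z up to 100 MΩ), then rounding to the 2 V/2¹⁶ ADC grid, after
  nearest-integer-stride decimation.  Across 100 noise realizations per
  condition, the 50 µs-window maximal-slope estimate has a strictly
  smaller 5–95 percentile spread than the adjacent-sample estimate at
  every rate where the window spans more than one sample (50–200 kHz),
  and the adjacent-sample estimate inflates with sampling rate while the
  window estimate stays within 10%.  At exactly 20 kHz the window *is*
  one sample, the two estimators are the same function, and their spreads
  coincide — equality, not improvement, is the correct expectation there.
* **EPSC trains** — homogeneous Poisson onsets (5 Hz over 60 s), unit-peak
  bi-exponential kernels (1−e^(−t/τ_on))·e^(−t/τ_off) with τ_on = 0.2 ms,
  τ_off = 2.5 ms, jittered multiplicatively (CV 0.3 on time constants,
  0.1 on amplitudes), summing linearly on colored noise (white noise
  low-passed at 1 kHz, SD set after filtering).  The default noise SD of
  0.1 of the mean unit peak puts typical events near 10 baseline SDs,
  the regime of whole-cell EPSC recordings in which exemplary events stand
  clearly beyond a −5 SD extraction line.  The generator emulates the
  *statistics* of a dendritic cable simulation (kinetic and amplitude
  variability from electrotonic filtering) without solving a cable
  equation: event amplitudes are free parameters, there is no
  driving-force nonlinearity, and kernel shapes are exactly
  bi-exponential.  Detection results on it therefore certify the
  detectors' signal-processing chain, not their behavior under dendritic
  filtering heterogeneity beyond what multiplicative jitter captures.

What passing the synthetic suites shows: the measurement, fitting,
detection and reduction code paths are numerically correct against
closed forms and independent oracles at realistic parameter scales.  What
it does not show: robustness to drifting baselines, seal instability,
correlated biological noise, or non-stationary event rates — none of
which the generators emulate.

## I/O

Text files are tab-separated (ATF-style, with the two-line "ATF 1.0"
header plus a quoted column-title line; headerless files are accepted and
the sniffing decision logged) or comma-separated.  Column 0 is time in ms;
dt is inferred from the first two rows and uniformity enforced to one part
in 10⁴.  Files written by the package title each column
`<channel>.<sweep>` so multi-sweep recordings round-trip; foreign files
map columns to channels, one sweep per file.  Times are written at full
float precision (so dt round-trips exactly); data values at a configurable
number of significant digits (default 9), and write→read→write is
byte-identical.  The HDF5 layout is `/channels/<i>` with attributes
`name`, `y_unit`, `dt_ms` and float64 datasets `sweep_<j>` (attribute
`t0_ms`), plus root attributes `format_version` and `meta_*`; round-trips
are bit-exact.  Binary vendor formats are out of scope; externally parsed
arrays enter through `recording_from_arrays`.

## Known limitations

* Averaging sweeps of unequal length is rejected for `align="none"`
  (peak alignment handles unequal lengths by trimming to the overlap).
* The LM backend is unbounded; parameter constraints are enforced on the
  seeds and checked on evaluation, not imposed during the search.
* `min–max` reduction emits device-independent data coordinates;
  rasterization and anti-aliasing are the plotting backend's concern.
* The Wang–Buzsáki integrator is fixed-step; adaptive stiffness control is
  unnecessary at the default 1 µs–2.5 µs steps but nothing warns below
  spike-resolving step sizes except a coarse dt > 10 µs warning.
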