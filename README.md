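# patchkit

A validated analysis core for patch-clamp electrophysiology.  It covers the
quantitative half of a typical intracellular-recording workflow — load
sweeps, place cursors, measure, fit, detect — as a plain Python library
with a batch command-line interface, for electrophysiologists and method
developers who need the algorithms without a GUI.

## What it computes

**Principal measurements.**  For a sweep *y(t)* with baseline mean *b* and
baseline-relative peak *A*: the 20–80% rise time (interpolated crossings of
0.2·|A| and 0.8·|A| before the peak), the half duration (full width at
0.5·|A|), maximal rising/decaying slopes d*V*/d*t* over a fixed derivative
interval (default 50 µs, robust to thermal and quantization noise at high
sampling rates), slope-threshold crossings, the extrapolated event "foot"
(intersection of the baseline with the line through the 20% and 80% rise
points), and latencies between events — including the synaptic latency
from presynaptic maximal d*V*/d*t* to postsynaptic foot.

**Model fitting.**  Levenberg–Marquardt least squares of the standard model
zoo — A·e^(−t/τ)+C, bi-exponentials (with and without onset delay), the
alpha synapse A·(t/τ)·e^(1−t/τ), Hodgkin–Huxley-style gated Na⁺
conductance waveforms A·(1−e^(−t/τ_m))^p·e^(−t/τ_h) (p = 1, 3), and a
Gaussian — with initial estimates derived automatically from the principal
measurements (or from log-linear regression for exponentials).  Data can
be rescaled to [0,1]×[0,1] before fitting; a fit is *successful* when the
rescaled sum of squared errors is ≤ 0.001.

**Event detection.**  A unit-peak template *p* of length *n* slides over
the recording *r*; at each position the straight-line fit
χ²(t_s) = Σ_k [r(t_s+k) − (m·p(t_k) + c)]² is solved with running sums.
The detection criterion is either the correlation between the optimally
scaled template and the data, or the scale factor normalized by the
standard error m/√(χ²_min/(n−1)).  Alternatively the recording is
deconvolved by the template via FFT, recovering the event-onset delta
train; the threshold is a multiple of the SD of a Gaussian fitted to the
criterion's all-point histogram.

**Display reduction.**  Min–max pixel-column downsampling: *n* samples
drawn into *w* columns become exactly 2w−1 segments with pixel coverage
identical to the naive polyline (worthwhile for n > 2w+2).

**Synthetic validation data.**  Analytic sine/exponential/Gaussian traces
with closed-form measurement values; a Wang–Buzsáki interneuron simulation
providing a realistic action potential, degraded with Johnson–Nyquist noise
√(4k_BTBZ) and 2 V/2¹⁶ ADC quantization; Poisson trains of bi-exponential
EPSCs (τ_onset = 0.2 ms, τ_decay = 2.5 ms, 5 Hz) with colored noise.

## Worked example

Simulate a 20 s EPSC train at 5 Hz, bootstrap a template from its large
events, and detect events by deconvolution:

```sh
$ patchkit simulate epsc-train --duration-s 20 --seed 7 --out rec.h5 --truth-out truth.tsv
wrote rec.h5
wrote truth.tsv
$ patchkit make-template rec.h5 --out template.csv
wrote template.csv (220 samples)
$ patchkit detect rec.h5 --template template.csv --method deconvolution \
      --out events.tsv --truth truth.tsv
108 events -> events.tsv
truth n=98 FP=10 FN=0 total_error_rate=0.102
$ head -4 events.tsv
onset_ms	peak_ms	criterion	accepted
141.05	142.15	-0.164788	1
346.1	347.2	-0.209839	1
459.8	460.9	-0.177809	1
```

The generator placed 98 events; at the default 4 SD deconvolution
threshold every one is recovered (FN=0) with 10 spurious detections
(FP=10), a total error rate of 10.2% against the ground-truth onsets at
2 ms tolerance.  The `criterion` column is the deconvolved onset-train
amplitude at each event (negative: inward current); `accepted` supports
GUI-less curation by editing the table.

The same works from Python:

```python
from patchkit import events, synthetic

trace, truth = synthetic.gen_epsc_train(duration_s=20, seed=7)
template = events.make_template(trace)
criterion = events.deconvolution_criterion(trace, template)
found = events.detect_events(criterion, threshold_sd=4.0,
                             min_interval_ms=0.5, direction="down")
rates = events.evaluate_detection(found, truth.onset_times)
```

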