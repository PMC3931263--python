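"""Spontaneous synaptic event detection.

Two detector families operate on a criterion trace derived from the
recording:

* **Sliding template matching** — at every window position the template
  ``p`` is scaled by ``m`` and offset by ``c`` to minimize the sum of
  squared errors against the data window (an ordinary straight-line fit of
  the window against the template, computed with running sums).  The
  detection criterion is either the linear correlation coefficient between
  the optimally scaled template and the data, or the scaling factor
  normalized by the standard error of the window fit.
* **Deconvolution** — the recording is modelled as the convolution of a
  delta train of event onsets with the template; dividing their spectra
  recovers an estimate of the onset train, low-pass filtered for
  regularization.  The detection threshold is a multiple of the SD of a
  Gaussian fitted to the all-point histogram of the criterion.

Events are contiguous supra-threshold runs of the criterion; detections are
benchmarked against generator ground truth by greedy nearest matching.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import Region, Trace, gaussian_sigma_ms
from .errors import DetectionError
from . import fitting, measurements as meas

__all__ = [
    "Template",
    "CriterionTrace",
    "Event",
    "EventList",
    "DetectionErrorRates",
    "make_template",
    "sliding_linear_fit",
    "template_criterion",
    "deconvolution_criterion",
    "histogram_gaussian_sd",
    "detect_events",
    "evaluate_detection",
]

log = logging.getLogger(__name__)


@dataclass
class Template:
    """Typical-event waveform, baseline 0, extremum normalized to +1."""

    waveform: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        peak = float(np.max(np.abs(self.waveform)))
        if not math.isclose(peak, 1.0, rel_tol=1e-9):
            raise ValueError("template must be normalized to unit extremum")
        if abs(self.waveform[0]) >= 0.05:
            raise ValueError("template must start near baseline (|p0| < 0.05)")

    @property
    def n(self) -> int:
        return self.waveform.size

    @property
    def peak_offset(self) -> int:
        """Samples from template start to its extremum."""
        return int(np.argmax(np.abs(self.waveform)))

    @property
    def rise_samples(self) -> int:
        """Samples between the 20% and 80% crossings before the extremum
        (used as the default event merge interval)."""
        w = np.abs(self.waveform)
        pk = self.peak_offset
        above20 = np.nonzero(w[:pk + 1] >= 0.2)[0]
        above80 = np.nonzero(w[:pk + 1] >= 0.8)[0]
        if above20.size == 0 or above80.size == 0:
            return max(1, pk)
        return max(1, int(above80[0] - above20[0]))


@dataclass
class CriterionTrace:
    """Per-window detection criterion aligned to window start indices."""

    values: np.ndarray
    method: str                      # correlation | scale | deconvolution
    dt: float
    t0: float
    noise_sd: float
    valid_range: Region
    peak_offset: int = 0             # samples from onset to the event peak

    def __post_init__(self) -> None:
        if self.method == "correlation":
            v = self.values[self.valid_range.slice()]
            if np.any(v < -1.0 - 1e-9) or np.any(v > 1.0 + 1e-9):
                raise ValueError("correlation criterion must lie in [-1, 1]")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be positive")


@dataclass
class Event:
    onset_index: int
    peak_index: int
    criterion_value: float
    accepted: bool = True


@dataclass
class EventList:
    events: list[Event]
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        onsets = [e.onset_index for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onset_times(self) -> np.ndarray:
        return self.t0 + self.dt * np.array([e.onset_index for e in self.events], float)

    def to_table(self) -> str:
        """Tab-separated table (onset_ms, peak_ms, criterion, accepted)."""
        lines = ["onset_ms\tpeak_ms\tcriterion\taccepted"]
        for e in self.events:
            lines.append(f"{self.t0 + self.dt * e.onset_index:.6g}\t"
                         f"{self.t0 + self.dt * e.peak_index:.6g}\t"
                         f"{e.criterion_value:.6g}\t{int(e.accepted)}")
        return "\n".join(lines) + "\n"


@dataclass
class DetectionErrorRates:
    n_true: int
    n_detected: int
    false_positives: int
    false_negatives: int
    tolerance_ms: float

    @property
    def total_error_rate(self) -> float:
        """(FP + FN) / n_true."""
        return (self.false_positives + self.false_negatives) / max(1, self.n_true)


# ------------------------------------------------------------ template build

def make_template(trace: Trace, k_sd: float = 5.0, pre_ms: float = 1.0,
                  post_ms: float = 10.0, polarity: str = "down",
                  baseline_region: Region | None = None) -> Template:
    """Bootstrap a template from large isolated events in the trace itself.

    Finds peaks beyond ``mean -/+ k_sd * SD`` (sign per ``polarity``),
    peak-aligns and averages the surrounding windows, fits the average to a
    delayed bi-exponential event model and returns the fitted curve
    normalized to unit extremum.
    """
    base_reg = baseline_region or Region(0, len(trace))
    base = meas.baseline(trace, base_reg)
    sign = -1.0 if polarity == "down" else 1.0
    y = sign * (trace.samples - base.mean)
    thr = k_sd * base.sd
    pre = int(round(pre_ms / trace.dt))
    post = int(round(post_ms / trace.dt))
    span = pre + post
    above = y > thr
    idx_above = np.nonzero(above)[0]
    if idx_above.size == 0:
        raise DetectionError(f"no peaks beyond {k_sd} SD; cannot bootstrap a template")
    # split supra-threshold samples into excursions, keep each excursion's
    # peak, then merge peaks closer than one window span (noise can split a
    # single event into several excursions)
    breaks = np.nonzero(np.diff(idx_above) > 1)[0]
    groups = np.split(idx_above, breaks + 1)
    candidates = sorted(g[np.argmax(y[g])] for g in groups)
    peaks: list[int] = []
    for p in candidates:
        if peaks and p - peaks[-1] < span:
            if y[p] > y[peaks[-1]]:
                peaks[-1] = p
        else:
            peaks.append(p)
    windows = [y[p - pre:p + post] for p in peaks
               if p - pre >= 0 and p + post <= len(trace)]
    if not windows:
        raise DetectionError("no candidate event fits within the trace bounds")
    avg = np.mean(windows, axis=0)
    avg -= np.mean(avg[:max(1, pre // 2)])
    fit_trace = Trace(avg, trace.dt, trace.y_unit)
    result = fitting.fit_model(fit_trace, Region(0, span), "biexp_with_delay")
    curve = fitting.evaluate_model("biexp_with_delay", result.params,
                                   trace.dt * np.arange(span))
    extremum = curve[np.argmax(np.abs(curve))]
    if extremum == 0:
        raise DetectionError("fitted template is identically zero")
    log.info("template from %d events: params=%s", len(windows), result.params)
    return Template(curve / extremum, trace.dt)


# ------------------------------------------------------ criterion computation

def _running_sums(r: np.ndarray, n: int):
    """Sliding window sums of r and r^2 for every window of length n."""
    c1 = np.concatenate([[0.0], np.cumsum(r)])
    c2 = np.concatenate([[0.0], np.cumsum(r * r)])
    sy = c1[n:] - c1[:-n]
    syy = c2[n:] - c2[:-n]
    return sy, syy


def sliding_linear_fit(trace: Trace, template: Template):
    """Optimal (m, c, chi2_min) of the straight-line fit r = m*p + c at
    every window position.

    Returns three arrays of length ``len(trace) - template.n + 1``; entry
    ``s`` describes the window starting at sample ``s``.  Computed with
    running sums plus one FFT cross-correlation, O(total samples).
    """
    if not math.isclose(template.dt, trace.dt, rel_tol=1e-9):
        raise ValueError("template dt must equal trace dt")
    n = template.n
    r = trace.samples
    if n > r.size:
        raise ValueError("template longer than trace")
    p = template.waveform
    sp = float(np.sum(p))
    spp = float(np.sum(p * p))
    denom = n * spp - sp * sp
    if denom <= 0:
        raise ValueError("zero-variance template")
    sy, syy = _running_sums(r, n)
    from scipy.signal import fftconvolve
    spy = fftconvolve(r, p[::-1], mode="valid")
    m = (n * spy - sp * sy) / denom
    c = (sy - m * sp) / n
    chi2 = syy - sy * sy / n - m * m * (spp - sp * sp / n)
    return m, c, np.maximum(chi2, 0.0)


def template_criterion(trace: Trace, template: Template,
                       method: str = "scale") -> CriterionTrace:
    """Sliding straight-line fit of the template to every trace window.

    ``method="correlation"`` returns the Pearson correlation between the
    window and the optimally scaled template (in [-1, 1]); ``"scale"``
    returns the scaling factor divided by the standard error of the window
    fit, sqrt(chi2_min / (n - 1)).  Runs in O(total samples) using running
    sums plus one FFT cross-correlation.
    """
    if not math.isclose(template.dt, trace.dt, rel_tol=1e-9):
        raise ValueError("template dt must equal trace dt")
    n = template.n
    r = trace.samples
    if n > r.size:
        raise ValueError("template longer than trace")
    p = template.waveform
    sp = float(np.sum(p))
    spp = float(np.sum(p * p))
    denom = n * spp - sp * sp
    if denom <= 0:
        raise ValueError("zero-variance template")
    sy, syy = _running_sums(r, n)
    from scipy.signal import fftconvolve
    spy = fftconvolve(r, p[::-1], mode="valid")
    m = (n * spy - sp * sy) / denom
    if method == "correlation":
        # Pearson r between the window and the optimally scaled template
        # m*p + c equals sign(m) * r(p, y) = |r(p, y)|: matching events of
        # either polarity drive the criterion toward +1.
        var_y = n * syy - sy * sy
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(n * spy - sp * sy) / np.sqrt(denom * var_y)
        corr = np.where(var_y > 0, corr, 0.0)
        values = np.clip(corr, 0.0, 1.0)
    elif method == "scale":
        chi2 = syy - sy * sy / n - m * m * (spp - sp * sp / n)
        chi2 = np.maximum(chi2, 1e-300)
        values = m / np.sqrt(chi2 / (n - 1))
    else:
        raise ValueError(f"unknown template-matching method {method!r}")
    full = np.zeros(r.size)
    full[:values.size] = values
    valid = Region(0, values.size)
    sd = histogram_gaussian_sd(values)
    return CriterionTrace(full, method, trace.dt, trace.t0, sd, valid,
                          template.peak_offset)


def deconvolution_criterion(trace: Trace, template: Template,
                            lowpass_fc_khz: float = 1.0,
                            noise_sd: float | None = None) -> CriterionTrace:
    """FFT deconvolution of the trace by the template.

    Returns the estimated event-onset train, Gaussian low-pass filtered at
    ``lowpass_fc_khz`` for regularization; near-zero template spectral
    magnitudes are floored at 1e-6 of the spectral maximum.  ``noise_sd``
    overrides the all-point-histogram estimate (needed for noise-free
    traces whose histogram is degenerate).
    """
    if not math.isclose(template.dt, trace.dt, rel_tol=1e-9):
        raise ValueError("template dt must equal trace dt")
    r = trace.samples
    n = r.size
    if template.n > n:
        raise ValueError("template longer than trace")
    p = np.zeros(n)
    p[:template.n] = template.waveform
    spec_r = np.fft.rfft(r)
    spec_p = np.fft.rfft(p)
    mag = np.abs(spec_p)
    floor = 1e-6 * float(np.max(mag))
    small = mag < floor
    if np.any(small):
        log.info("deconvolution: flooring %d near-zero spectral bins", int(small.sum()))
        # keep the phase, lift the magnitude
        phase = np.where(mag > 0, spec_p / np.maximum(mag, 1e-300), 1.0)
        spec_p = np.where(small, phase * floor, spec_p)
    freqs = np.fft.rfftfreq(n, trace.dt)  # kHz (time base in ms)
    sigma_t = gaussian_sigma_ms(lowpass_fc_khz)
    transfer = np.exp(-2.0 * math.pi ** 2 * sigma_t ** 2 * freqs ** 2)
    f_prime = np.fft.irfft(spec_r / spec_p * transfer, n)
    sd = noise_sd if noise_sd is not None else histogram_gaussian_sd(f_prime)
    return CriterionTrace(f_prime, "deconvolution", trace.dt, trace.t0, sd,
                          Region(0, n), template.peak_offset)


def histogram_gaussian_sd(values: np.ndarray, min_values: int = 1000) -> float:
    """SD of a Gaussian fitted to the all-point histogram of ``values``.

    Bins follow the Freedman-Diaconis rule; the Gaussian is fitted only to
    bins within two interquartile ranges of the mode so that event tails do
    not inflate the noise estimate.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_values:
        raise ValueError(f"need at least {min_values} values, got {v.size}")
    q25, q75 = np.percentile(v, [25, 75])
    iqr = q75 - q25
    if iqr <= 0 or np.ptp(v) == 0:
        raise ValueError("degenerate (near-constant) input")
    bin_width = 2.0 * iqr / v.size ** (1.0 / 3.0)
    nbins = max(10, int(math.ceil(np.ptp(v) / bin_width)))
    counts, edges = np.histogram(v, bins=min(nbins, 100000))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode = centers[int(np.argmax(counts))]
    sel = np.abs(centers - mode) <= 2.0 * iqr
    csel, xsel = counts[sel].astype(float), centers[sel]
    if xsel.size < 5:
        raise ValueError("too few central bins to fit")
    # histogram-as-trace so the shared model machinery does the fit
    hist_trace = Trace(csel, float(xsel[1] - xsel[0]), "count", t0=float(xsel[0]))
    init = np.array([float(np.max(csel)), mode, max(iqr / 1.349, bin_width)])
    result = fitting.fit_model(hist_trace, Region(0, xsel.size), "gaussian",
                               initial=init - np.array([0.0, float(xsel[0]), 0.0]))
    sd = abs(float(result.params[2]))
    if not (sd > 0 and math.isfinite(sd)):
        raise ValueError("gaussian fit of the all-point histogram failed")
    return sd


# ---------------------------------------------------------------- detection

def detect_events(criterion: CriterionTrace, threshold_sd: float,
                  min_interval_ms: float, direction: str = "up") -> EventList:
    """Threshold the criterion trace into an event list.

    Contiguous supra-threshold runs become events (event time = criterion
    extremum within the run); runs separated by less than
    ``min_interval_ms`` are merged keeping the larger criterion peak.
    ``direction`` selects the sign of the excursions ("up", "down", or
    "both" on the absolute value).
    """
    thr = threshold_sd * criterion.noise_sd
    v = criterion.values
    if direction == "up":
        score = v
    elif direction == "down":
        score = -v
    elif direction == "both":
        score = np.abs(v)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    mask = np.zeros(v.size, dtype=bool)
    sl = criterion.valid_range.slice()
    mask[sl] = score[sl] >= thr
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return EventList([], criterion.dt, criterion.t0)
    min_gap = max(1, int(round(min_interval_ms / criterion.dt)))
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1)
    # merge runs closer than the minimum interval
    merged: list[np.ndarray] = [runs[0]]
    for run in runs[1:]:
        if run[0] - merged[-1][-1] < min_gap:
            merged[-1] = np.concatenate([merged[-1], run])
        else:
            merged.append(run)
    events = []
    for run in merged:
        k = run[int(np.argmax(score[run]))]
        events.append(Event(int(k), int(k) + criterion.peak_offset, float(v[k])))
    return EventList(events, criterion.dt, criterion.t0)


def evaluate_detection(events: EventList, truth_onsets_ms: np.ndarray,
                       tolerance_ms: float = 2.0) -> DetectionErrorRates:
    """Greedy one-to-one matching of detections to ground-truth onsets.

    Detections are matched nearest-first within ``tolerance_ms``; leftover
    detections are false positives, leftover truths false negatives.  Ties
    resolve toward the earlier truth.
    """
    if tolerance_ms < 0:
        raise ValueError("tolerance must be non-negative")
    truth = np.asarray(truth_onsets_ms, dtype=float)
    det = events.onset_times
    if truth.size and np.any(np.diff(truth) < 0):
        raise ValueError("truth onsets must be sorted")
    pairs = []
    for i, td in enumerate(det):
        for j, tt in enumerate(truth):
            d = abs(td - tt)
            if d <= tolerance_ms:
                pairs.append((d, j, i))  # sort key favours earlier truth on ties
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    n_match = 0
    for d, j, i in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n_match += 1
    return DetectionErrorRates(truth.size, len(det),
                               len(det) - n_match, truth.size - n_match,
                               tolerance_ms)
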