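"""Principal kinetic measurements on patch-clamp sweeps.

Baseline mean/SD, (moving-average) peak, fractional rise time, half
duration (full width at half-maximal amplitude), maximal slopes of rise and
decay at a fixed derivative interval (default 50 µs), slope-threshold
crossing, the extrapolated "foot" of an event, and latencies between two
measured events.

Conventions
-----------
* Fraction crossings are located by linear interpolation between the
  bracketing samples, searching backward from the peak (last crossing
  before the peak), which keeps the estimate robust to noise before event
  onset.
* The fixed slope window is ``w = max(1, round(window_ms / dt))`` samples;
  at sampling intervals coarser than the window this degrades gracefully to
  the adjacent-sample difference.
* Baseline SD is the population SD; it doubles as the noise estimate for
  event-detection thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Region, Trace
from .errors import MeasurementUndefinedError, RegionError

__all__ = [
    "BaselineResult",
    "PeakResult",
    "RiseTimeResult",
    "HalfDurationResult",
    "SlopeResult",
    "MeasurementSet",
    "baseline",
    "peak",
    "rise_time",
    "half_duration",
    "max_slope",
    "threshold_crossing",
    "foot_time",
    "latency",
    "measure_all",
    "slope_window_samples",
]

DEFAULT_SLOPE_WINDOW_MS = 0.05  # 50 µs derivative interval


@dataclass
class BaselineResult:
    mean: float
    sd: float
    region: Region


@dataclass
class PeakResult:
    value: float            # baseline-subtracted
    absolute_value: float
    index: int
    direction: str
    n_average: int

    @property
    def magnitude(self) -> float:
        return abs(self.value)


@dataclass
class RiseTimeResult:
    t_low: float
    t_high: float
    frac_low: float
    frac_high: float

    @property
    def duration(self) -> float:
        return self.t_high - self.t_low


@dataclass
class HalfDurationResult:
    t_left: float
    t_right: float

    @property
    def width(self) -> float:
        return self.t_right - self.t_left


@dataclass
class SlopeResult:
    value: float        # y-units per ms
    at_time: float      # ms, left edge of the extremal window
    window: float       # derivative interval in ms actually used


@dataclass
class MeasurementSet:
    """All principal measurements of one event on one trace."""

    baseline: BaselineResult
    peak: PeakResult
    rise: RiseTimeResult | None = None
    half: HalfDurationResult | None = None
    slope_rise: SlopeResult | None = None
    slope_decay: SlopeResult | None = None
    threshold: tuple[float, float] | None = None  # (time ms, y value)
    foot: float | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        """Flatten to a key->value table for CSV export."""
        out: dict[str, float] = {
            "baseline_mean": self.baseline.mean,
            "baseline_sd": self.baseline.sd,
            "peak_value": self.peak.value,
            "peak_abs": self.peak.absolute_value,
            "peak_index": self.peak.index,
        }
        if self.rise is not None:
            out.update(rise_t_low=self.rise.t_low, rise_t_high=self.rise.t_high,
                       rise_time=self.rise.duration)
        if self.half is not None:
            out.update(half_t_left=self.half.t_left, half_t_right=self.half.t_right,
                       half_duration=self.half.width)
        if self.slope_rise is not None:
            out.update(max_slope_rise=self.slope_rise.value,
                       max_slope_rise_t=self.slope_rise.at_time)
        if self.slope_decay is not None:
            out.update(max_slope_decay=self.slope_decay.value,
                       max_slope_decay_t=self.slope_decay.at_time)
        if self.threshold is not None:
            out.update(threshold_t=self.threshold[0], threshold_value=self.threshold[1])
        if self.foot is not None:
            out["foot_t"] = self.foot
        return out


def baseline(trace: Trace, region: Region) -> BaselineResult:
    """Mean and population SD over the baseline cursor region."""
    region.validate(len(trace))
    seg = trace.samples[region.slice()]
    return BaselineResult(float(np.mean(seg)), float(np.std(seg)), region)


def peak(trace: Trace, base: BaselineResult, region: Region,
         direction: str = "both", n_average: int = 1) -> PeakResult:
    """Extremum of the n_average-point moving average within the region.

    ``direction`` is ``"up"`` (maximum), ``"down"`` (minimum) or ``"both"``
    (largest baseline-subtracted magnitude; ties resolve to the earlier
    index).  The returned ``value`` is relative to the baseline mean.
    """
    region.validate(len(trace))
    if n_average < 1 or n_average % 2 == 0:
        raise ValueError(f"n_average must be odd and >= 1, got {n_average}")
    if n_average > len(region):
        raise ValueError("n_average exceeds region length")
    seg = trace.samples[region.slice()]
    if n_average > 1:
        kernel = np.full(n_average, 1.0 / n_average)
        smooth = np.convolve(seg, kernel, mode="valid")
        offset = n_average // 2
    else:
        smooth, offset = seg, 0
    rel = smooth - base.mean
    if direction == "up":
        k = int(np.argmax(rel))
    elif direction == "down":
        k = int(np.argmin(rel))
    elif direction == "both":
        k = int(np.argmax(np.abs(rel)))  # argmax takes the first = earlier tie
    else:
        raise ValueError(f"unknown direction {direction!r}")
    idx = region.begin + offset + k
    value = float(rel[k])
    if n_average > 1:
        # value comes from the moving average; the index is refined to the
        # raw extremum inside the smoothing window so downstream rise/decay
        # searches start at the actual peak sample
        lo = max(region.begin, idx - offset)
        hi = min(region.end, idx + offset + 1)
        raw = trace.samples[lo:hi] - base.mean
        k_raw = int(np.argmax(raw)) if value >= 0 else int(np.argmin(raw))
        idx = lo + k_raw
    return PeakResult(value, value + base.mean, idx, direction, n_average)


def _cross_backward(samples: np.ndarray, start: int, stop: int, level: float,
                    sign: float, dt: float, t0: float) -> float | None:
    """Last crossing of ``level`` before ``start`` (searching toward ``stop``).

    ``sign`` is +1 for upward-going events, -1 for downward: samples are
    compared after multiplying by ``sign`` so one code path serves both
    polarities.  Returns the interpolated crossing time or None.
    """
    y = sign * samples
    lv = sign * level
    for i in range(start, stop, -1):
        if y[i - 1] < lv <= y[i]:
            frac = (lv - y[i - 1]) / (y[i] - y[i - 1])
            return t0 + dt * (i - 1 + frac)
        if y[i - 1] == lv:
            return t0 + dt * (i - 1)
    return None


def _cross_forward(samples: np.ndarray, start: int, stop: int, level: float,
                   sign: float, dt: float, t0: float) -> float | None:
    """First crossing of ``level`` at or after ``start`` going down-slope."""
    y = sign * samples
    lv = sign * level
    for i in range(start, stop - 1):
        if y[i] >= lv > y[i + 1]:
            frac = (y[i] - lv) / (y[i] - y[i + 1])
            return t0 + dt * (i + frac)
    return None


def rise_time(trace: Trace, base: BaselineResult, pk: PeakResult,
              frac_low: float = 0.2, frac_high: float = 0.8,
              region: Region | None = None) -> RiseTimeResult:
    """Time between the frac_low and frac_high crossings on the rising phase.

    Crossings are the last ones before the peak, interpolated linearly.
    """
    if not (0 < frac_low < frac_high < 1):
        raise ValueError("need 0 < frac_low < frac_high < 1")
    if pk.value == 0:
        raise MeasurementUndefinedError("rise_time", "peak amplitude is zero")
    sign = 1.0 if pk.value > 0 else -1.0
    lo = region.begin if region is not None else 0
    rel = trace.samples - base.mean
    t_low = _cross_backward(rel, pk.index, lo, frac_low * abs(pk.value), sign,
                            trace.dt, trace.t0)
    t_high = _cross_backward(rel, pk.index, lo, frac_high * abs(pk.value), sign,
                             trace.dt, trace.t0)
    if t_low is None or t_high is None:
        raise MeasurementUndefinedError("rise_time", "fraction level never crossed")
    return RiseTimeResult(t_low, t_high, frac_low, frac_high)


def half_duration(trace: Trace, base: BaselineResult, pk: PeakResult,
                  region: Region | None = None) -> HalfDurationResult:
    """Full width at half-maximal (baseline-subtracted) amplitude."""
    if pk.value == 0:
        raise MeasurementUndefinedError("half_duration", "peak amplitude is zero")
    sign = 1.0 if pk.value > 0 else -1.0
    lo = region.begin if region is not None else 0
    hi = region.end if region is not None else len(trace)
    rel = trace.samples - base.mean
    level = 0.5 * abs(pk.value)
    t_left = _cross_backward(rel, pk.index, lo, level, sign, trace.dt, trace.t0)
    t_right = _cross_forward(rel, pk.index, hi, level, sign, trace.dt, trace.t0)
    if t_left is None or t_right is None:
        raise MeasurementUndefinedError("half_duration", "half level not crossed on both sides")
    return HalfDurationResult(t_left, t_right)


def slope_window_samples(dt: float, window_ms: float = DEFAULT_SLOPE_WINDOW_MS) -> int:
    """Number of samples closest to the requested derivative interval (>= 1)."""
    return max(1, int(round(window_ms / dt)))


def _windowed_slopes(trace: Trace, region: Region, window_ms: float):
    region.validate(len(trace))
    w = slope_window_samples(trace.dt, window_ms)
    seg = trace.samples[region.slice()]
    if len(seg) < w + 1:
        raise RegionError(f"region too short for slope window of {w} samples")
    slopes = (seg[w:] - seg[:-w]) / (w * trace.dt)
    return slopes, w


def max_slope(trace: Trace, region: Region, window_ms: float = DEFAULT_SLOPE_WINDOW_MS,
              sign: str = "rise") -> SlopeResult:
    """Extremal fixed-interval slope (y-units/ms) within the region.

    The derivative is ``(y(t+w) - y(t)) / w`` with ``w`` the number of
    samples closest to ``window_ms``; ``sign="rise"`` takes the maximum,
    ``"decay"`` the minimum.
    """
    slopes, w = _windowed_slopes(trace, region, window_ms)
    if sign == "rise":
        k = int(np.argmax(slopes))
    elif sign == "decay":
        k = int(np.argmin(slopes))
    else:
        raise ValueError(f"sign must be 'rise' or 'decay', got {sign!r}")
    return SlopeResult(float(slopes[k]), trace.time_at(region.begin + k), w * trace.dt)


def threshold_crossing(trace: Trace, region: Region, rate_threshold: float,
                       window_ms: float = DEFAULT_SLOPE_WINDOW_MS) -> tuple[float, float]:
    """First sample in the region whose fixed-window slope >= rate_threshold.

    Returns ``(time_ms, y_value)`` of that sample; this is the slope-based
    action-potential threshold of the principal-measurement table.
    """
    slopes, _w = _windowed_slopes(trace, region, window_ms)
    hits = np.nonzero(slopes >= rate_threshold)[0]
    if hits.size == 0:
        raise MeasurementUndefinedError("threshold", f"slope never reaches {rate_threshold}")
    i = region.begin + int(hits[0])
    return trace.time_at(i), float(trace.samples[i])


def foot_time(trace: Trace, base: BaselineResult, rise: RiseTimeResult) -> float:
    """Extrapolated event onset: intersection of the baseline with the
    straight line through the 20% and 80% rise points."""
    if rise.t_high == rise.t_low:
        raise MeasurementUndefinedError("foot", "degenerate rise (t_high == t_low)")
    span = rise.frac_high - rise.frac_low
    return rise.t_low - (rise.frac_low / span) * (rise.t_high - rise.t_low)


def latency(source: MeasurementSet, target: MeasurementSet,
            mode: str = "max_slope_to_foot", dt: float | None = None) -> float:
    """Latency (ms) between two measured events.

    Modes: ``peak_to_peak`` (requires ``dt`` and shared time base via
    ``extras['t0']`` or peak times stored in extras), ``half_rise``
    (midpoints between the half-duration edges... here: time of half-maximal
    amplitude on the rising phase), and the synaptic default
    ``max_slope_to_foot`` — presynaptic maximal rising slope to postsynaptic
    extrapolated foot.
    """
    if mode == "peak_to_peak":
        ts = source.extras.get("peak_time")
        tt = target.extras.get("peak_time")
        if ts is None or tt is None:
            raise ValueError("peak_to_peak latency needs extras['peak_time'] in both sets")
        return tt - ts
    if mode == "half_rise":
        if source.half is None or target.half is None:
            raise ValueError("half_rise latency needs half-duration results in both sets")
        return target.half.t_left - source.half.t_left
    if mode == "max_slope_to_foot":
        if source.slope_rise is None:
            raise ValueError("max_slope_to_foot latency needs slope_rise in the source set")
        if target.foot is None:
            raise ValueError("max_slope_to_foot latency needs foot time in the target set")
        return target.foot - source.slope_rise.at_time
    raise ValueError(f"unknown latency mode {mode!r}")


def measure_all(trace: Trace, cursors: dict[str, Region],
                direction: str = "both", n_average: int = 1,
                frac_low: float = 0.2, frac_high: float = 0.8,
                slope_window_ms: float = DEFAULT_SLOPE_WINDOW_MS,
                rate_threshold: float | None = None) -> MeasurementSet:
    """Run every principal measurement with a shared baseline and peak.

    ``cursors`` must contain ``"baseline"`` and ``"peak"`` regions; slopes
    are measured within the peak region.  Individual failures are re-raised
    as :class:`MeasurementUndefinedError` naming the failed measurement;
    rise/half/foot failures on traces where they are genuinely undefined
    leave those fields ``None`` only if the caller catches the error.
    """
    base = baseline(trace, cursors["baseline"])
    peak_region = cursors["peak"]
    pk = peak(trace, base, peak_region, direction, n_average)
    if pk.value == 0:
        raise MeasurementUndefinedError("peak", "no deflection from baseline")
    ms = MeasurementSet(baseline=base, peak=pk)
    ms.extras["peak_time"] = trace.time_at(pk.index)
    ms.rise = rise_time(trace, base, pk, frac_low, frac_high, region=peak_region)
    ms.half = half_duration(trace, base, pk, region=peak_region)
    ms.slope_rise = max_slope(trace, peak_region, slope_window_ms, "rise")
    ms.slope_decay = max_slope(trace, peak_region, slope_window_ms, "decay")
    if ms.rise.frac_low == 0.2 and ms.rise.frac_high == 0.8:
        ms.foot = foot_time(trace, base, ms.rise)
    if rate_threshold is not None:
        ms.threshold = threshold_crossing(trace, peak_region, rate_threshold, slope_window_ms)
    return ms
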