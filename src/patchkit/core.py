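"""In-memory data model for multi-sweep intracellular recordings.

A :class:`Trace` is one uniformly sampled sweep (time in ms, signal in mV or
pA).  Sweeps are grouped into named :class:`Channel` objects, which in turn
form a :class:`Recording`.  Cursor pairs delimiting regions of interest are
half-open sample-index windows (:class:`Region`).

The module also provides the trace-level operations of the analysis
workflow: sweep selection, concatenation, (peak-aligned) averaging, baseline
subtraction and zero-phase low-pass filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import IncompatibleTracesError, RegionError

__all__ = [
    "Trace",
    "Channel",
    "Recording",
    "Region",
    "SweepSelection",
    "select_sweeps",
    "concatenate_sweeps",
    "average_sweeps",
    "subtract_baseline",
    "lowpass_filter",
    "gaussian_sigma_ms",
]


@dataclass
class Trace:
    """One sweep: uniformly sampled signal values.

    Parameters
    ----------
    samples : array-like of float
        Signal values, at least one sample.
    dt : float
        Sampling interval in ms, strictly positive.
    y_unit : str
        Signal unit label, e.g. ``"mV"`` or ``"pA"``.
    t0 : float
        Time of the first sample in ms; sample *i* lies at ``t0 + i*dt``.
    """

    samples: np.ndarray
    dt: float
    y_unit: str = "mV"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not (self.dt > 0):
            raise ValueError(f"dt must be > 0, got {self.dt}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms."""
        return self.t0 + self.dt * np.arange(self.samples.size)

    def time_at(self, index: float) -> float:
        """Time (ms) of a possibly fractional sample index."""
        return self.t0 + self.dt * index

    def index_at(self, time_ms: float) -> int:
        """Nearest sample index for a time in ms (round half up)."""
        return int(math.floor((time_ms - self.t0) / self.dt + 0.5))

    def with_samples(self, samples: np.ndarray, t0: float | None = None) -> "Trace":
        return Trace(samples, self.dt, self.y_unit, self.t0 if t0 is None else t0)


@dataclass
class Region:
    """Half-open sample-index window ``[begin, end)`` between two cursors."""

    begin: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.begin < self.end):
            raise RegionError(f"invalid region [{self.begin}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.begin

    def validate(self, n: int) -> "Region":
        if self.end > n:
            raise RegionError(f"region [{self.begin}, {self.end}) exceeds trace length {n}")
        return self

    def slice(self) -> slice:
        return slice(self.begin, self.end)


@dataclass
class Channel:
    """A named, ordered list of sweeps sharing dt and y_unit."""

    name: str
    sweeps: list[Trace]

    def __post_init__(self) -> None:
        if len(self.sweeps) < 1:
            raise ValueError("a channel needs at least one sweep")
        dt0, unit0 = self.sweeps[0].dt, self.sweeps[0].y_unit
        for tr in self.sweeps[1:]:
            if not math.isclose(tr.dt, dt0, rel_tol=1e-12):
                raise IncompatibleTracesError(
                    f"channel '{self.name}': sweeps mix dt {dt0} and {tr.dt}")
            if tr.y_unit != unit0:
                raise IncompatibleTracesError(
                    f"channel '{self.name}': sweeps mix units {unit0!r} and {tr.y_unit!r}")

    @property
    def dt(self) -> float:
        return self.sweeps[0].dt

    @property
    def y_unit(self) -> str:
        return self.sweeps[0].y_unit


@dataclass
class Recording:
    """Top-level container: ordered channels plus free-form metadata."""

    channels: list[Channel]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("a recording needs at least one channel")


@dataclass
class SweepSelection:
    """Ordered set of sweep indices into one channel."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        self.indices = tuple(self.indices)
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")


def select_sweeps(
    channel: Channel,
    predicate: Callable[[Trace], bool] | None = None,
    indices: Iterable[int] | None = None,
) -> SweepSelection:
    """Select sweeps by a quantitative predicate or by explicit indices.

    Exactly one of ``predicate`` / ``indices`` must be given.  Explicit
    indices are sorted and deduplicated; a predicate preserves sweep order.
    """
    if (predicate is None) == (indices is None):
        raise ValueError("give exactly one of predicate or indices")
    n = len(channel.sweeps)
    if indices is not None:
        idx = sorted(set(int(i) for i in indices))
        for i in idx:
            if not 0 <= i < n:
                raise IndexError(f"sweep index {i} out of range 0..{n - 1}")
        return SweepSelection(tuple(idx))
    return SweepSelection(tuple(i for i, tr in enumerate(channel.sweeps) if predicate(tr)))


def concatenate_sweeps(traces: Sequence[Trace]) -> Trace:
    """Join sweeps into one uninterrupted trace (t0 from the first)."""
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    first = traces[0]
    for tr in traces[1:]:
        if not math.isclose(tr.dt, first.dt, rel_tol=1e-12):
            raise IncompatibleTracesError(f"cannot concatenate dt {first.dt} with {tr.dt}")
        if tr.y_unit != first.y_unit:
            raise IncompatibleTracesError(
                f"cannot concatenate units {first.y_unit!r} with {tr.y_unit!r}")
    return Trace(np.concatenate([tr.samples for tr in traces]),
                 first.dt, first.y_unit, first.t0)


def _peak_index(samples: np.ndarray, region: Region, direction: str) -> int:
    seg = samples[region.slice()]
    if direction == "up":
        return region.begin + int(np.argmax(seg))
    if direction == "down":
        return region.begin + int(np.argmin(seg))
    raise ValueError(f"unknown peak direction {direction!r}")


def average_sweeps(
    traces: Sequence[Trace],
    align: str = "none",
    direction: str = "up",
    search: Region | None = None,
) -> Trace:
    """Pointwise mean of sweeps, optionally after peak alignment.

    ``align="none"`` requires equal lengths.  ``align="peak"`` shifts each
    sweep so that its (sample-resolution) peak index within ``search``
    coincides, then trims the result to the window covered by every sweep.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    first = traces[0]
    for tr in traces[1:]:
        if not math.isclose(tr.dt, first.dt, rel_tol=1e-12) or tr.y_unit != first.y_unit:
            raise IncompatibleTracesError("averaging requires shared dt and y_unit")
    if align == "none":
        n = len(first)
        if any(len(tr) != n for tr in traces):
            raise IncompatibleTracesError("align='none' requires equal sweep lengths")
        return first.with_samples(np.mean([tr.samples for tr in traces], axis=0))
    if align != "peak":
        raise ValueError(f"unknown align mode {align!r}")
    peaks = []
    for tr in traces:
        reg = (search or Region(0, len(tr))).validate(len(tr))
        peaks.append(_peak_index(tr.samples, reg, direction))
    # overlap window relative to each sweep's peak
    pre = min(peaks)
    post = min(len(tr) - p for tr, p in zip(traces, peaks))
    stack = [tr.samples[p - pre:p + post] for tr, p in zip(traces, peaks)]
    t0 = first.time_at(peaks[0] - pre)
    return first.with_samples(np.mean(stack, axis=0), t0=t0)


def subtract_baseline(trace: Trace, region: Region) -> Trace:
    """Subtract the mean over the baseline region from every sample."""
    region.validate(len(trace))
    return trace.with_samples(trace.samples - float(np.mean(trace.samples[region.slice()])))


def gaussian_sigma_ms(fc_khz: float) -> float:
    """Kernel SD (ms) of the Gaussian filter with -3 dB point at fc (kHz)."""
    return math.sqrt(math.log(2.0)) / (2.0 * math.pi * fc_khz)


def lowpass_filter(trace: Trace, fc_khz: float) -> Trace:
    """Zero-phase Gaussian low-pass filter.

    The filter is a Gaussian smoothing kernel whose -3 dB (half-power)
    frequency is ``fc_khz``.  Zero phase means measured latencies are not
    shifted by filtering.  DC gain is exactly 1.
    """
    nyquist = 0.5 / trace.dt
    if not (0 < fc_khz < nyquist):
        raise ValueError(f"fc must lie in (0, {nyquist}) kHz, got {fc_khz}")
    sigma = gaussian_sigma_ms(fc_khz) / trace.dt
    return trace.with_samples(gaussian_filter1d(trace.samples, sigma, mode="nearest"))
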