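"""Least-squares model fitting with measurement-derived initial estimates.

The model zoo covers the standard parametric shapes of cellular
neurophysiology: mono-/bi-exponentials, a delayed bi-exponential (product of
rising and decaying exponentials), the alpha synapse function, Hodgkin-
Huxley-style gated Na+ conductance waveforms, and a Gaussian.  Each model
knows how to seed its own parameters from the principal measurements
(peak, rise time, half duration, foot time) or, for plain exponentials,
from a linear regression on log-transformed data.

Optimization is Levenberg-Marquardt least squares.  Data may be rescaled so
that time (relative to the fit region start) and signal both span [0, 1];
the 0.001 sum-of-squared-errors success criterion is always evaluated on
the y-rescaled residuals so that one threshold applies across models and
units.  Parameters are reported in natural units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core import Region, Trace
from .errors import FitError, InitializationError, MeasurementUndefinedError
from . import measurements as meas

__all__ = [
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "RescaleTransform",
    "ValidationReport",
    "MODELS",
    "get_model",
    "evaluate_model",
    "init_params",
    "fit_model",
    "validate_fit_grid",
    "SUCCESS_SSE",
]

SUCCESS_SSE = 1e-3  # on the [0,1]-rescaled trace


# ---------------------------------------------------------------- model zoo

@dataclass
class ModelSpec:
    name: str
    param_names: tuple[str, ...]
    units: tuple[str, ...]
    evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    init: Callable[[Trace, Region], np.ndarray]
    lower: np.ndarray
    upper: np.ndarray
    # reference parameters for validation grids (physiologically plausible)
    reference: np.ndarray
    # duration (ms) that comfortably contains the event for given params
    span: Callable[[np.ndarray], float]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def check(self, params: Sequence[float]) -> np.ndarray:
        p = np.asarray(params, dtype=float)
        if p.shape != (self.n_params,):
            raise ValueError(f"{self.name} expects {self.n_params} parameters")
        if np.any(p < self.lower) or np.any(p > self.upper):
            raise ValueError(f"{self.name}: parameters {p} violate constraints")
        return p


def _monoexp(p, t):
    A, tau, C = p
    return A * np.exp(-t / tau) + C


def _biexp(p, t):
    A1, t1, A2, t2, C = p
    return A1 * np.exp(-t / t1) + A2 * np.exp(-t / t2) + C


def _biexp_delay(p, t):
    A, t1, t2, d = p
    out = np.zeros_like(t, dtype=float)
    m = t >= d
    tt = t[m] - d
    out[m] = A * (1.0 - np.exp(-tt / t1)) * np.exp(-tt / t2)
    return out


def _alpha(p, t):
    A, tau = p
    return A * (t / tau) * np.exp(1.0 - t / tau)


def _hh_na(p, t):
    A, tm, th = p
    return A * (1.0 - np.exp(-t / tm)) ** 3 * np.exp(-t / th)


def _two_gated(p, t):
    A, tm, th = p
    return A * (1.0 - np.exp(-t / tm)) * np.exp(-t / th)


def _gaussian(p, t):
    A, mu, sigma = p
    return A * np.exp(-((t - mu) ** 2) / (2.0 * sigma ** 2))


def _gated_peak(tm: float, th: float, power: int) -> float:
    """Peak value of (1-exp(-t/tm))^power * exp(-t/th) (amplitude 1)."""
    u = tm / (tm + power * th)       # e^{-t_peak/tm} at the extremum
    return (1.0 - u) ** power * u ** (tm / th)


def _gated_peak_time(tm: float, th: float, power: int) -> float:
    """Time of that peak."""
    u = tm / (tm + power * th)
    return -tm * math.log(u)


# ----------------------------------------------------- measurement contexts

def _measure_event(trace: Trace, region: Region):
    """Baseline from the first region sample, peak over the region.

    The event models fitted with measurement seeding all start at baseline
    at the region's left cursor; a single-sample baseline keeps the seed
    exact even when the rising phase is much faster than the region span.
    """
    base = meas.baseline(trace, Region(region.begin, region.begin + 1))
    pk = meas.peak(trace, base, region, direction="both", n_average=1)
    return base, pk


def _tail_mean(y: np.ndarray, frac: float = 0.1) -> float:
    k = max(1, int(len(y) * frac))
    return float(np.mean(y[-k:]))


def _log_linear_tau(t: np.ndarray, y: np.ndarray, frac: float = 0.05):
    """Slope-based (tau, amplitude) from ln(y) vs t on a decaying segment.

    Only samples with ``y > frac * max(y)`` enter the regression, which
    avoids taking the log of near-zero or negative values.
    """
    ymax = float(np.max(y))
    mask = y > frac * ymax
    if np.count_nonzero(mask) < 2:
        raise InitializationError("too few samples above the log-regression floor")
    b, a = np.polyfit(t[mask], np.log(y[mask]), 1)
    if b >= 0:
        raise InitializationError("log-linear regression found a non-decaying segment")
    return -1.0 / b, math.exp(a)


def _decay_tau(trace: Trace, region: Region, pk, base) -> float:
    """Time constant of the decay after the peak, by log-linear regression."""
    sign = 1.0 if pk.value > 0 else -1.0
    y = sign * (trace.samples[pk.index:region.end] - base.mean)
    t = trace.dt * np.arange(len(y))
    tau, _amp = _log_linear_tau(t, np.maximum(y, 0.0) + 0.0, frac=0.05)
    return tau


# ------------------------------------------------------------- init per model

def _init_monoexp(trace: Trace, region: Region) -> np.ndarray:
    y = trace.samples[region.slice()]
    t = trace.dt * np.arange(len(y))
    C = _tail_mean(y)
    resid = y - C
    sign = 1.0 if resid[0] >= 0 else -1.0
    tau, amp = _log_linear_tau(t, np.maximum(sign * resid, 0.0), frac=0.05)
    return np.array([sign * amp, tau, C])


def _init_biexp(trace: Trace, region: Region) -> np.ndarray:
    y = trace.samples[region.slice()]
    t = trace.dt * np.arange(len(y))
    C = _tail_mean(y)
    resid = y - C
    sign = 1.0 if resid[0] >= 0 else -1.0
    z = np.maximum(sign * resid, 0.0)
    # slow component from the second half, fast from the residual early part
    half = len(y) // 2
    tau2, amp2 = _log_linear_tau(t[half:], z[half:] + 1e-300, frac=0.05)
    fast = z - amp2 * np.exp(-t / tau2)
    try:
        tau1, amp1 = _log_linear_tau(t[:half], np.maximum(fast[:half], 0.0), frac=0.05)
    except InitializationError:
        tau1, amp1 = tau2 / 5.0, 0.5 * amp2
    return np.array([sign * amp1, tau1, sign * amp2, tau2, C])


def _init_biexp_delay(trace: Trace, region: Region) -> np.ndarray:
    base, pk = _measure_event(trace, region)
    rise = meas.rise_time(trace, base, pk, 0.2, 0.8, region=region)
    delta = meas.foot_time(trace, base, rise) - trace.time_at(region.begin)
    delta = max(delta, 0.0)
    tau2 = _decay_tau(trace, region, pk, base)
    tau1 = max(rise.duration / 1.4, trace.dt)
    kernel_peak = _gated_peak(tau1, tau2, 1)
    A = pk.value / kernel_peak
    return np.array([A, tau1, tau2, delta])


def _init_alpha(trace: Trace, region: Region) -> np.ndarray:
    base, pk = _measure_event(trace, region)
    tau = trace.time_at(pk.index) - trace.time_at(region.begin)
    if tau <= 0:
        raise InitializationError("alpha synapse: peak at the region start")
    return np.array([pk.value, tau])


def _init_hh_na(trace: Trace, region: Region) -> np.ndarray:
    base, pk = _measure_event(trace, region)
    rise = meas.rise_time(trace, base, pk, 0.2, 0.8, region=region)
    tm = max(rise.duration / 1.4, trace.dt)
    th = _decay_tau(trace, region, pk, base)
    A = pk.value / _gated_peak(tm, th, 3)
    return np.array([A, tm, th])


def _init_two_gated(trace: Trace, region: Region) -> np.ndarray:
    base, pk = _measure_event(trace, region)
    rise = meas.rise_time(trace, base, pk, 0.2, 0.8, region=region)
    tm = max(rise.duration, trace.dt)
    th = _decay_tau(trace, region, pk, base)
    A = pk.value / _gated_peak(tm, th, 1)
    return np.array([A, tm, th])


def _init_gaussian(trace: Trace, region: Region) -> np.ndarray:
    base, pk = _measure_event(trace, region)
    mu = trace.time_at(pk.index) - trace.time_at(region.begin)
    try:
        half = meas.half_duration(trace, base, pk, region=region)
        sigma = half.width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    except MeasurementUndefinedError:
        sigma = len(region) * trace.dt / 6.0  # pulse clipped by the region edge
    return np.array([pk.value, mu, sigma])


_POS = 1e-9
_INF = np.inf


def _spec(name, names, units, fn, init, lower, upper, reference, span):
    return ModelSpec(name, tuple(names), tuple(units), fn, init,
                     np.array(lower, float), np.array(upper, float),
                     np.array(reference, float), span)


MODELS: dict[str, ModelSpec] = {m.name: m for m in [
    _spec("monoexp", ("A", "tau", "C"), ("y", "ms", "y"), _monoexp, _init_monoexp,
          [-_INF, _POS, -_INF], [_INF, _INF, _INF], [1.0, 10.0, 0.0],
          lambda p: 8.0 * p[1]),
    _spec("biexp", ("A1", "tau1", "A2", "tau2", "C"), ("y", "ms", "y", "ms", "y"),
          _biexp, _init_biexp,
          [-_INF, _POS, -_INF, _POS, -_INF], [_INF, _INF, _INF, _INF, _INF],
          [0.5, 2.0, 0.5, 10.0, 0.0], lambda p: 8.0 * max(p[1], p[3])),
    _spec("biexp_with_delay", ("A", "tau1", "tau2", "delta"), ("y", "ms", "ms", "ms"),
          _biexp_delay, _init_biexp_delay,
          [-_INF, _POS, _POS, 0.0], [_INF, _INF, _INF, _INF],
          [1.0, 1.0, 10.0, 1.0], lambda p: p[3] + 12.0 * p[2] + 5.0 * p[1]),
    _spec("alpha_synapse", ("A", "tau"), ("y", "ms"), _alpha, _init_alpha,
          [-_INF, _POS], [_INF, _INF], [1.0, 5.0], lambda p: 12.0 * p[1]),
    _spec("hh_na_conductance", ("A", "tau_m", "tau_h"), ("y", "ms", "ms"),
          _hh_na, _init_hh_na,
          [-_INF, _POS, _POS], [_INF, _INF, _INF], [1.0, 0.5, 3.0],
          lambda p: 12.0 * p[2] + 5.0 * p[1]),
    _spec("two_gated_na", ("A", "tau_m", "tau_h"), ("y", "ms", "ms"),
          _two_gated, _init_two_gated,
          [-_INF, _POS, _POS], [_INF, _INF, _INF], [1.0, 0.5, 3.0],
          lambda p: 12.0 * p[2] + 5.0 * p[1]),
    _spec("gaussian", ("A", "mu", "sigma"), ("y", "ms", "ms"), _gaussian, _init_gaussian,
          [-_INF, -_INF, _POS], [_INF, _INF, _INF], [1.0, 10.0, 2.0],
          lambda p: p[1] + 6.0 * p[2]),
]}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {', '.join(sorted(MODELS))}")


def evaluate_model(model: ModelSpec | str, params: Sequence[float],
                   times: np.ndarray) -> np.ndarray:
    """Evaluate a named model at the given times (ms from region start)."""
    m = get_model(model) if isinstance(model, str) else model
    p = m.check(params)
    return m.evaluate(p, np.asarray(times, dtype=float))


def init_params(model: ModelSpec | str, trace: Trace, region: Region) -> np.ndarray:
    """Initial parameter estimate from principal measurements / log regression."""
    m = get_model(model) if isinstance(model, str) else model
    region.validate(len(trace))
    try:
        p0 = m.init(trace, region)
    except (MeasurementUndefinedError, InitializationError) as exc:
        raise InitializationError(f"{m.name}: {exc}") from exc
    return np.clip(p0, m.lower, m.upper)


# ---------------------------------------------------------------- fitting

@dataclass
class FitOptions:
    max_iterations: int = 2048
    tolerance: float = 1e-8
    rescale: bool = True


@dataclass
class RescaleTransform:
    """Affine map taking (time, signal) into the unit square and back."""

    x_offset: float
    x_scale: float
    y_offset: float
    y_scale: float

    def __post_init__(self) -> None:
        if self.x_scale <= 0 or self.y_scale <= 0:
            raise ValueError("rescale factors must be positive")

    @classmethod
    def from_data(cls, t: np.ndarray, y: np.ndarray) -> "RescaleTransform":
        xs = float(t[-1] - t[0]) or 1.0
        ys = float(np.ptp(y)) or 1.0
        return cls(float(t[0]), xs, float(np.min(y)), ys)

    def apply(self, t, y):
        return (np.asarray(t) - self.x_offset) / self.x_scale, \
               (np.asarray(y) - self.y_offset) / self.y_scale

    def invert(self, ts, ys):
        return np.asarray(ts) * self.x_scale + self.x_offset, \
               np.asarray(ys) * self.y_scale + self.y_offset


@dataclass
class FitResult:
    model: str
    params: np.ndarray
    initial_params: np.ndarray
    sse: float                 # in squared y-units over the fit region
    sse_scaled: float          # on the [0,1]-rescaled trace
    iterations: int
    converged: bool
    success: bool              # sse_scaled <= SUCCESS_SSE and converged
    rescale: RescaleTransform | None = None

    def as_dict(self) -> dict[str, float | str]:
        m = get_model(self.model)
        out: dict[str, float | str] = {"model": self.model}
        out.update({k: float(v) for k, v in zip(m.param_names, self.params)})
        out.update(sse=self.sse, sse_scaled=self.sse_scaled,
                   iterations=self.iterations, converged=self.converged,
                   success=self.success)
        return out


def fit_model(trace: Trace, region: Region, model: ModelSpec | str,
              options: FitOptions | None = None,
              initial: Sequence[float] | None = None) -> FitResult:
    """Levenberg-Marquardt fit of a model to the trace over the region.

    Times are taken relative to the region start.  With ``options.rescale``
    the residuals are evaluated in the unit square (see module docstring);
    parameters are optimized and reported in natural units either way.
    """
    m = get_model(model) if isinstance(model, str) else model
    options = options or FitOptions()
    region.validate(len(trace))
    if len(region) <= m.n_params:
        raise ValueError("fit region must contain more samples than parameters")
    y = trace.samples[region.slice()]
    t = trace.dt * np.arange(len(y))
    if initial is None:
        p0 = init_params(m, trace, region)
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (m.n_params,):
            raise ValueError(f"{m.name} expects {m.n_params} initial parameters")
    xform = RescaleTransform.from_data(t, y)
    y_div = xform.y_scale if options.rescale else 1.0

    def residuals(p):
        with np.errstate(over="ignore", invalid="ignore"):
            r = (m.evaluate(p, t) - y) / y_div
        return np.where(np.isfinite(r), r, 1e6)

    try:
        res = least_squares(residuals, p0, method="lm",
                            xtol=options.tolerance, ftol=options.tolerance,
                            gtol=options.tolerance, max_nfev=options.max_iterations)
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitError(f"least-squares search failed for {m.name}: {exc}") from exc
    with np.errstate(over="ignore", invalid="ignore"):
        final = m.evaluate(res.x, t)
    resid = final - y
    if not np.all(np.isfinite(resid)):
        raise FitError(f"{m.name}: non-finite model values at the solution")
    sse = float(np.sum(resid ** 2))
    sse_scaled = float(np.sum((resid / xform.y_scale) ** 2))
    converged = bool(res.status > 0)
    return FitResult(m.name, res.x, p0, sse, sse_scaled, int(res.nfev),
                     converged, converged and sse_scaled <= SUCCESS_SSE,
                     xform if options.rescale else None)


# ------------------------------------------------------ validation harness

@dataclass
class ValidationReport:
    model: str
    traces_tested: int
    mean_sse: float           # mean scaled SSE over all tested traces
    pct_unsuccessful: float   # percentage with scaled SSE > SUCCESS_SSE

    def __post_init__(self) -> None:
        assert 0.0 <= self.pct_unsuccessful <= 100.0


def _grid_params(m: ModelSpec, n_traces: int, seed: int, cv: float) -> np.ndarray:
    from .synthetic import randomize_params  # local import avoids a cycle
    # multiplicative jitter must preserve the sign of every reference
    # parameter, so the grid floors all bounds at a small positive value
    lower = np.maximum(m.lower, 1e-3 * np.abs(m.reference))
    return randomize_params(m.reference, cv, n_traces, seed,
                            lower=lower, upper=m.upper)


def validate_fit_grid(model: ModelSpec | str, n_traces: int, seed: int,
                      init_strategy: str = "measurements",
                      cv: float = 0.3, n_samples: int = 1000) -> ValidationReport:
    """Fit noise-free synthetic traces and report the unsuccessful-fit rate.

    Traces are generated from the model with parameters drawn as
    ``reference * N(1, cv)`` per parameter (redrawn until inside the model
    constraints).  ``init_strategy="measurements"`` seeds each fit from the
    model's own measurement-based estimator; ``"average_of_grid"`` seeds
    every fit from the mean parameter vector of the grid (the contrast
    condition).  A fit counts as unsuccessful when its scaled SSE exceeds
    0.001 or when initialization/optimization raises.
    """
    m = get_model(model) if isinstance(model, str) else model
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if init_strategy not in ("measurements", "average_of_grid"):
        raise ValueError(f"unknown init strategy {init_strategy!r}")
    grid = _grid_params(m, n_traces, seed, cv)
    grid_mean = grid.mean(axis=0)
    n_bad = 0
    sses = []
    for p_true in grid:
        span = m.span(p_true)
        dt = span / n_samples
        t = dt * np.arange(n_samples)
        trace = Trace(m.evaluate(p_true, t), dt, "pA")
        region = Region(0, n_samples)
        try:
            initial = None if init_strategy == "measurements" else grid_mean
            fr = fit_model(trace, region, m, initial=initial)
            sses.append(fr.sse_scaled)
            if not fr.success:
                n_bad += 1
        except (InitializationError, FitError):
            n_bad += 1
            sses.append(math.nan)
    finite = [s for s in sses if math.isfinite(s)]
    return ValidationReport(m.name, n_traces,
                            float(np.mean(finite)) if finite else math.nan,
                            100.0 * n_bad / n_traces)
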