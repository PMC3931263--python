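"""Synthetic-data generators used to validate every analysis algorithm.

Four families:

* analytic traces (sine, mono-exponential, Gaussian pulse) whose principal
  measurements have closed-form expected values;
* a realistic action-potential waveform from a single-compartment
  Wang-Buzsaki interneuron model, degraded with Johnson-Nyquist thermal
  noise, ADC quantization and down-sampling, for stress-testing the
  fixed-interval slope estimator;
* randomized parameter grids (multiplicative Gaussian factors) for the
  fit-convergence and measurement-validation harnesses;
* Poisson trains of bi-exponential EPSCs with colored noise for
  benchmarking the event detectors.

All randomness flows through explicit integer seeds; the same seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Trace, lowpass_filter
from .errors import PatchkitError

__all__ = [
    "NoiseModel",
    "EventTrainTruth",
    "WBParams",
    "gen_sine",
    "gen_monoexp",
    "gen_gaussian_pulse",
    "randomize_params",
    "thermal_noise_sd",
    "add_noise_and_quantize",
    "resample",
    "simulate_wang_buzsaki",
    "ap_waveform",
    "gen_epsc_train",
    "BOLTZMANN",
]

BOLTZMANN = 1.380649e-23  # J/K

_VOLT_FACTORS = {"V": 1.0, "mV": 1e-3, "uV": 1e-6, "µV": 1e-6}


# ------------------------------------------------------- analytic families

def gen_sine(A: float, f: float, n: int, dt: float) -> Trace:
    """A*sin(2*pi*f*x); f in cycles/ms, x = i*dt in ms."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    x = dt * np.arange(n)
    return Trace(A * np.sin(2.0 * math.pi * f * x), dt, "mV")


def gen_monoexp(A: float, tau: float, C: float, n: int, dt: float) -> Trace:
    """A*exp(-t/tau) + C."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = dt * np.arange(n)
    return Trace(A * np.exp(-t / tau) + C, dt, "mV")


def gen_gaussian_pulse(A: float, mu: float, sigma: float, n: int, dt: float) -> Trace:
    """A*exp(-(t-mu)^2 / (2 sigma^2))."""
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    t = dt * np.arange(n)
    return Trace(A * np.exp(-((t - mu) ** 2) / (2.0 * sigma ** 2)), dt, "mV")


def randomize_params(reference, cv, count: int, seed: int,
                     lower=None, upper=None, max_redraw: int = 1000) -> np.ndarray:
    """Parameter sets ``reference * N(1, cv)``, redrawn until within bounds.

    ``cv`` may be a scalar or a per-parameter sequence of multiplier SDs.
    Returns an array of shape ``(count, n_params)``; deterministic per seed.
    """
    ref = np.asarray(reference, dtype=float)
    cvs = np.broadcast_to(np.asarray(cv, dtype=float), ref.shape)
    if np.any(cvs < 0):
        raise ValueError("cv must be non-negative")
    if count < 1:
        raise ValueError("count must be >= 1")
    lo = -np.inf * np.ones_like(ref) if lower is None else np.asarray(lower, float)
    hi = np.inf * np.ones_like(ref) if upper is None else np.asarray(upper, float)
    rng = np.random.default_rng(seed)
    out = np.empty((count, ref.size))
    for i in range(count):
        for _ in range(max_redraw):
            p = ref * rng.normal(1.0, cvs)
            if np.all(p >= lo) and np.all(p <= hi):
                out[i] = p
                break
        else:
            raise PatchkitError("could not draw parameters inside constraints")
    return out


# -------------------------------------------- thermal noise + quantization

@dataclass
class NoiseModel:
    """Johnson-Nyquist thermal noise plus ADC quantization.

    ``impedance_mohm`` in MOhm, ``bandwidth_khz`` the Nyquist frequency in
    kHz, ``full_scale_v`` the ADC range in volts over ``bits`` bits.
    """

    impedance_mohm: float = 0.0
    temperature_k: float = 298.0
    bandwidth_khz: float = 100.0
    full_scale_v: float = 2.0
    bits: int = 16

    def __post_init__(self) -> None:
        if self.impedance_mohm < 0 or self.temperature_k <= 0 or self.bandwidth_khz <= 0:
            raise ValueError("invalid noise-model parameters")

    @property
    def quantum_v(self) -> float:
        return self.full_scale_v / 2 ** self.bits


def thermal_noise_sd(noise: NoiseModel) -> float:
    """RMS thermal noise sqrt(4 kB T B Z) in volts (Z MOhm, B kHz inputs)."""
    return math.sqrt(4.0 * BOLTZMANN * noise.temperature_k
                     * noise.bandwidth_khz * 1e3 * noise.impedance_mohm * 1e6)


def add_noise_and_quantize(trace: Trace, noise: NoiseModel, seed: int) -> Trace:
    """Add white thermal noise, then round to the ADC grid.

    The trace's y-unit must be convertible to volts (V/mV/uV); noise is
    added and quantization applied in volts, the result converted back.
    """
    try:
        factor = _VOLT_FACTORS[trace.y_unit]
    except KeyError:
        raise ValueError(f"cannot convert unit {trace.y_unit!r} to volts")
    rng = np.random.default_rng(seed)
    v = trace.samples * factor
    sd = thermal_noise_sd(noise)
    if sd > 0:
        v = v + rng.normal(0.0, sd, v.size)
    q = noise.quantum_v
    v = np.round(v / q) * q
    return trace.with_samples(v / factor)


def resample(trace: Trace, new_rate_khz: float) -> Trace:
    """Decimate to a lower sampling rate by the nearest-integer stride.

    No interpolation: output samples are a subset of the input.  The actual
    resulting dt (stride * dt) is reported exactly.
    """
    old_rate = 1.0 / trace.dt
    if new_rate_khz > old_rate * (1 + 1e-12):
        raise ValueError("upsampling is not supported")
    stride = max(1, int(round(old_rate / new_rate_khz)))
    return Trace(trace.samples[::stride].copy(), trace.dt * stride,
                 trace.y_unit, trace.t0)


# -------------------------------------------- Wang-Buzsaki interneuron model

@dataclass
class WBParams:
    """Single-compartment Wang-Buzsaki interneuron parameters.

    Conductances in mS/cm^2, capacitance in uF/cm^2, current in pA spread
    over ``area_cm2``; with the default area of 1e-4 cm^2 a 100 pA step is
    a 1 uA/cm^2 density, which drives repetitive firing.
    """

    c_m: float = 1.0
    g_leak: float = 0.1
    g_na: float = 35.0
    g_k: float = 9.0
    i_inj_pa: float = 100.0
    duration_ms: float = 100.0
    dt: float = 0.001
    area_cm2: float = 1e-4
    e_na: float = 55.0
    e_k: float = -90.0
    e_leak: float = -65.0
    phi: float = 5.0


def _wb_rates(v: float):
    # sodium activation (instantaneous), inactivation h, potassium n
    dv = v + 35.0
    a_m = 0.1 * dv / (1.0 - math.exp(-dv / 10.0)) if abs(dv) > 1e-9 else 1.0
    b_m = 4.0 * math.exp(-(v + 60.0) / 18.0)
    a_h = 0.07 * math.exp(-(v + 58.0) / 20.0)
    b_h = 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)
    dn = v + 34.0
    a_n = 0.01 * dn / (1.0 - math.exp(-dn / 10.0)) if abs(dn) > 1e-9 else 0.1
    b_n = 0.125 * math.exp(-(v + 44.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def simulate_wang_buzsaki(params: WBParams | None = None) -> Trace:
    """Membrane potential (mV) of the Wang-Buzsaki model under constant current.

    Fixed-step 4th-order Runge-Kutta integration; sodium activation is at
    steady state, h and n kinetics are sped up by the temperature factor
    phi = 5, as in the published model.  Deterministic.
    """
    p = params or WBParams()
    if p.dt > 0.01:
        import warnings
        warnings.warn("dt > 0.01 ms may be unstable for the spiking dynamics")
    i_density = p.i_inj_pa * 1e-6 / p.area_cm2  # pA -> uA/cm^2

    def deriv(v, h, n):
        a_m, b_m, a_h, b_h, a_n, b_n = _wb_rates(v)
        m_inf = a_m / (a_m + b_m)
        i_na = p.g_na * m_inf ** 3 * h * (v - p.e_na)
        i_k = p.g_k * n ** 4 * (v - p.e_k)
        i_l = p.g_leak * (v - p.e_leak)
        dv = (i_density - i_na - i_k - i_l) / p.c_m
        dh = p.phi * (a_h * (1.0 - h) - b_h * h)
        dn = p.phi * (a_n * (1.0 - n) - b_n * n)
        return dv, dh, dn

    v = -64.0
    a_m, b_m, a_h, b_h, a_n, b_n = _wb_rates(v)
    h = a_h / (a_h + b_h)
    n = a_n / (a_n + b_n)
    n_steps = int(round(p.duration_ms / p.dt))
    out = np.empty(n_steps + 1)
    out[0] = v
    dt = p.dt
    for i in range(n_steps):
        dv1, dh1, dn1 = deriv(v, h, n)
        dv2, dh2, dn2 = deriv(v + 0.5 * dt * dv1, h + 0.5 * dt * dh1, n + 0.5 * dt * dn1)
        dv3, dh3, dn3 = deriv(v + 0.5 * dt * dv2, h + 0.5 * dt * dh2, n + 0.5 * dt * dn2)
        dv4, dh4, dn4 = deriv(v + dt * dv3, h + dt * dh3, n + dt * dn3)
        v += (dt / 6.0) * (dv1 + 2 * dv2 + 2 * dv3 + dv4)
        h += (dt / 6.0) * (dh1 + 2 * dh2 + 2 * dh3 + dh4)
        n += (dt / 6.0) * (dn1 + 2 * dn2 + 2 * dn3 + dn4)
        if not math.isfinite(v) or abs(v) > 500:
            raise PatchkitError(f"integration blew up at step {i}")
        out[i + 1] = v
    return Trace(out, p.dt, "mV")


def ap_waveform(dt: float = 0.0025, pre_ms: float = 2.0, post_ms: float = 3.0) -> Trace:
    """One clean action potential from the Wang-Buzsaki model.

    Simulates 100 ms of repetitive firing at 100 pA (default 400 kHz grid)
    and cuts a window around the *second* spike so that the stimulus onset
    transient is excluded.  This is the packaged reference waveform for the
    slope-estimator benchmarks.
    """
    tr = simulate_wang_buzsaki(WBParams(duration_ms=100.0, dt=dt))
    above = tr.samples > 0.0
    # spike peaks = local maxima of supra-0 mV excursions
    starts = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    ends = np.nonzero(~above[1:] & above[:-1])[0] + 1
    if len(starts) < 2 or len(ends) < 2:
        raise PatchkitError("fewer than two spikes in the reference simulation")
    peaks = [s + int(np.argmax(tr.samples[s:e])) for s, e in zip(starts, ends)]
    pk = peaks[1]
    i0 = pk - int(round(pre_ms / dt))
    i1 = pk + int(round(post_ms / dt))
    return Trace(tr.samples[i0:i1].copy(), dt, "mV")


# ----------------------------------------------------------- EPSC trains

@dataclass
class EventTrainTruth:
    """Ground truth for a generated synaptic event train."""

    onset_times: np.ndarray   # ms, sorted
    amplitudes: np.ndarray    # pA (negative = inward)
    tau_onsets: np.ndarray    # ms, per event
    tau_decays: np.ndarray    # ms, per event

    def __len__(self) -> int:
        return self.onset_times.size


def epsc_kernel(tau_onset: float, tau_decay: float, dt: float,
                duration_ms: float | None = None) -> np.ndarray:
    """Unit-peak bi-exponential kernel (1-exp(-t/t_on)) * exp(-t/t_off)."""
    if duration_ms is None:
        duration_ms = 5.0 * tau_onset + 8.0 * tau_decay
    t = dt * np.arange(max(2, int(round(duration_ms / dt))))
    k = (1.0 - np.exp(-t / tau_onset)) * np.exp(-t / tau_decay)
    return k / np.max(k)


def gen_epsc_train(duration_s: float = 60.0, rate_hz: float = 5.0,
                   tau_onset: float = 0.2, tau_decay: float = 2.5,
                   amp: float = -1.0, cv_tau: float = 0.3, cv_amp: float = 0.1,
                   noise_fc_khz: float = 1.0, noise_sd: float = 0.1,
                   dt: float = 0.05, seed: int = 0) -> tuple[Trace, EventTrainTruth]:
    """Poisson train of bi-exponential EPSCs on colored noise.

    Onsets are a homogeneous Poisson process (default 5 Hz over 60 s); each
    event is a unit-peak bi-exponential kernel scaled by its own amplitude,
    with per-event time constants and amplitudes jittered by multiplicative
    N(1, cv) factors (defaults 0.3 for taus, 0.1 for amplitudes).  Events
    sum linearly.  Colored noise is white Gaussian noise low-pass filtered
    at ``noise_fc_khz`` and rescaled to ``noise_sd`` after filtering.  The
    default amplitude of -1 pA with noise SD 0.1 puts typical event peaks
    near 10 baseline SDs — the regime of whole-cell EPSC recordings where
    exemplary events stand clearly beyond a mean - 5 SD extraction line.
    """
    if duration_s <= 0 or rate_hz <= 0 or dt <= 0:
        raise ValueError("duration, rate and dt must be positive")
    rng = np.random.default_rng(seed)
    duration_ms = duration_s * 1e3
    n = int(round(duration_ms / dt))
    # Poisson onsets via exponential inter-event intervals
    mean_iei_ms = 1e3 / rate_hz
    times = []
    t = rng.exponential(mean_iei_ms)
    while t < duration_ms:
        times.append(t)
        t += rng.exponential(mean_iei_ms)
    onsets = np.asarray(times)
    n_ev = onsets.size
    taus_on = tau_onset * _positive_normal(rng, cv_tau, n_ev)
    taus_off = tau_decay * _positive_normal(rng, cv_tau, n_ev)
    amps = amp * _positive_normal(rng, cv_amp, n_ev)
    samples = np.zeros(n)
    for t_on, a, to, td in zip(onsets, amps, taus_on, taus_off):
        i0 = int(round(t_on / dt))
        k = a * epsc_kernel(to, td, dt)
        i1 = min(n, i0 + k.size)
        if i1 > i0:
            samples[i0:i1] += k[:i1 - i0]
    if noise_sd > 0:
        white = rng.normal(0.0, 1.0, n)
        colored = lowpass_filter(Trace(white, dt, "pA"), noise_fc_khz).samples
        colored *= noise_sd / np.std(colored)
        samples += colored
    truth = EventTrainTruth(onsets, amps, taus_on, taus_off)
    return Trace(samples, dt, "pA"), truth


def _positive_normal(rng, cv: float, size: int) -> np.ndarray:
    """Multiplicative N(1, cv) factors redrawn until positive."""
    if cv == 0:
        return np.ones(size)
    out = rng.normal(1.0, cv, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(1.0, cv, int(bad.sum()))
        bad = out <= 0
    return out
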