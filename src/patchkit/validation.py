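"""Validation harnesses tying the synthetic generators to the algorithms.

Three suites, all fully deterministic under an integer seed:

* :func:`validate_measurements` — randomized analytic traces (sine,
  mono-exponential, Gaussian) whose principal measurements have closed-form
  expected values; a trace passes when every measurement agrees with the
  analytic value to one sampling point (time-like results within one
  sampling interval, value-like results within the signal change across one
  interval).
* :func:`validate_fit_grid` (re-exported from :mod:`patchkit.fitting`) —
  fit-convergence grids.
* :func:`slope_spread_table` — Monte-Carlo spread of the maximal-slope
  estimators on the packaged action-potential waveform under thermal and
  quantization noise, across sampling rates and source impedances.
"""

from __future__ import annotations

import math

import numpy as np

from . import measurements as meas
from . import synthetic as syn
from .core import Region
from .fitting import validate_fit_grid  # noqa: F401  (re-export)

__all__ = ["validate_measurements", "slope_spread_table", "validate_fit_grid"]

N_PER_TRACE = 10_000


def _check_sine(A: float, f: float) -> list[str]:
    """Principal measurements of A*sin(2*pi*f*x) over one period."""
    n = N_PER_TRACE
    dt = 1.0 / (f * n)
    tr = syn.gen_sine(A, f, n, dt)
    base = meas.baseline(tr, Region(0, 1))  # sin(0) = 0: exact baseline
    region = Region(0, n)
    pk = meas.peak(tr, base, region, direction="up")
    rise = meas.rise_time(tr, base, pk)
    half = meas.half_duration(tr, base, pk)
    sl_r = meas.max_slope(tr, region, window_ms=dt, sign="rise")
    sl_d = meas.max_slope(tr, region, window_ms=dt, sign="decay")
    w = 2.0 * math.pi * f
    tol_t = dt                       # one sampling interval
    tol_y = A * w * dt               # max signal change across one interval
    tol_slope = A * w * w * dt       # max slope change across one interval
    errors = []
    if abs(pk.value - A) > tol_y:
        errors.append(f"peak {pk.value} vs {A}")
    expect_rise = (math.asin(0.8) - math.asin(0.2)) / w
    if abs(rise.duration - expect_rise) > tol_t:
        errors.append(f"rise {rise.duration} vs {expect_rise}")
    expect_half = 2.0 * (math.asin(1.0) - math.asin(0.5)) / w
    if abs(half.width - expect_half) > tol_t:
        errors.append(f"half {half.width} vs {expect_half}")
    if abs(sl_r.value - A * w) > tol_slope:
        errors.append(f"max slope {sl_r.value} vs {A * w}")
    if abs(sl_d.value + A * w) > tol_slope:
        errors.append(f"max decay {sl_d.value} vs {-A * w}")
    return errors


def _check_monoexp_threshold(A: float, tau: float) -> list[str]:
    """Slope-threshold crossing on a time-reversed exponential decay.

    Reversing A*exp(-t/tau) gives an exponential rise whose slope increases
    monotonically, so the first crossing of a rate threshold R has the
    closed form t* = T + tau*ln(R*tau/A).
    """
    n = N_PER_TRACE
    span = 5.0 * tau
    dt = span / n
    tr = syn.gen_monoexp(A, tau, 0.0, n, dt)
    rev = tr.with_samples(tr.samples[::-1].copy())
    T = (n - 1) * dt
    rate = 0.3 * A / tau  # below the maximal slope A/tau, so a crossing exists
    t_cross, _val = meas.threshold_crossing(rev, Region(0, n), rate, window_ms=dt)
    expect = T + tau * math.log(rate * tau / A)
    if abs(t_cross - expect) > dt:
        return [f"threshold crossing {t_cross} vs {expect}"]
    return []


def _check_gaussian_baseline(A: float, mu: float, sigma: float) -> list[str]:
    """Baseline mean over (roughly) [mu-sigma, mu+sigma] of a Gaussian pulse.

    The expected value is the erf integral over the sampled window extended
    by half a step on each side (midpoint rule), which is exact to O(dt^2)
    for any window placement; the window is clipped to the trace.
    """
    n = N_PER_TRACE
    span = mu + 6.0 * sigma
    dt = span / n
    tr = syn.gen_gaussian_pulse(A, mu, sigma, n, dt)
    i_lo = max(0, int(round((mu - sigma) / dt)))
    i_hi = min(n, int(round((mu + sigma) / dt)))
    base = meas.baseline(tr, Region(i_lo, i_hi))
    n_win = i_hi - i_lo
    z_a = (i_lo * dt - 0.5 * dt - mu) / (sigma * math.sqrt(2.0))
    z_b = ((i_hi - 1) * dt + 0.5 * dt - mu) / (sigma * math.sqrt(2.0))
    expect = (A * sigma * math.sqrt(math.pi / 2.0)
              * (math.erf(z_b) - math.erf(z_a)) / (n_win * dt))
    tol_y = A * math.exp(-0.5) / sigma * dt  # |f'| at mu +/- sigma, one step
    if abs(base.mean - expect) > tol_y:
        return [f"baseline {base.mean} vs {expect}"]
    return []


def validate_measurements(n_traces: int = 1000, seed: int = 1) -> dict:
    """Randomized analytic-trace validation of the principal measurements.

    ``n_traces`` traces are split evenly over the three analytic families;
    family parameters are references multiplied by N(1, 0.3) draws.
    Returns per-family counts of traces whose measurements all matched the
    analytic values to one sampling point.
    """
    per = n_traces // 3
    counts = {}
    sine_p = syn.randomize_params([10.0, 1.0], 0.3, per, seed,
                                  lower=[0.1, 0.01])
    fails = [e for A, f in sine_p for e in _check_sine(A, f)]
    counts["sine"] = {"n": per, "n_failed": len(fails), "examples": fails[:3]}
    exp_p = syn.randomize_params([5.0, 10.0], 0.3, per, seed + 1,
                                 lower=[0.1, 0.1])
    fails = [e for A, tau in exp_p for e in _check_monoexp_threshold(A, tau)]
    counts["monoexp"] = {"n": per, "n_failed": len(fails), "examples": fails[:3]}
    gauss_p = syn.randomize_params([1.0, 10.0, 2.0], 0.3,
                                   n_traces - 2 * per, seed + 2,
                                   lower=[0.01, 0.5, 0.05])
    fails = [e for A, mu, s in gauss_p for e in _check_gaussian_baseline(A, mu, s)]
    counts["gaussian"] = {"n": n_traces - 2 * per, "n_failed": len(fails),
                          "examples": fails[:3]}
    return counts


def slope_spread_table(n_realizations: int = 100, seed: int = 1,
                       rates_khz=(20.0, 50.0, 100.0, 200.0),
                       impedances_mohm=(10.0, 100.0)) -> list[dict]:
    """Spread of maximal-slope estimates on the packaged AP waveform.

    For every sampling rate and impedance, ``n_realizations`` traces are
    degraded with thermal noise (bandwidth = the rate's Nyquist frequency)
    and 2 V / 2^16 quantization after decimation; the maximal rising slope
    is estimated with the adjacent-sample difference and with the fixed
    50 us window.  Rows report the 5-95 percentile spread and mean of both
    estimators (mV/ms = V/s).
    """
    ap = syn.ap_waveform()
    rows = []
    rng = np.random.default_rng(seed)
    for z in impedances_mohm:
        for rate in rates_khz:
            ds = syn.resample(ap, rate)
            nm = syn.NoiseModel(impedance_mohm=z, bandwidth_khz=rate / 2.0)
            region = Region(0, len(ds))
            adj, win = [], []
            for _ in range(n_realizations):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                noisy = syn.add_noise_and_quantize(ds, nm, sub_seed)
                adj.append(meas.max_slope(noisy, region, window_ms=noisy.dt).value)
                win.append(meas.max_slope(noisy, region, window_ms=0.05).value)
            p5a, p95a = np.percentile(adj, [5, 95])
            p5w, p95w = np.percentile(win, [5, 95])
            rows.append({
                "rate_khz": rate,
                "impedance_mohm": z,
                "window_samples": meas.slope_window_samples(ds.dt),
                "adjacent_mean": float(np.mean(adj)),
                "window_mean": float(np.mean(win)),
                "adjacent_spread": float(p95a - p5a),
                "window_spread": float(p95w - p5w),
            })
    return rows
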