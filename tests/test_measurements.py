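import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchkit import measurements as m
from patchkit import synthetic as syn
from patchkit.core import Region, Trace
from patchkit.errors import MeasurementUndefinedError


@pytest.fixture(scope="module")
def sine10():
    """A=10, f=1 sine over one period, 10^4 samples (the reference trace)."""
    return syn.gen_sine(10.0, 1.0, 10_000, 1e-4)


def _measure_sine(trace):
    base = m.baseline(trace, Region(0, 1))
    pk = m.peak(trace, base, Region(0, len(trace)), "up")
    return base, pk


class TestBaseline:
    def test_constant(self):
        r = m.baseline(Trace([5.0] * 20, 0.1), Region(3, 17))
        assert r.mean == 5.0 and r.sd == 0.0

    def test_simple_mean(self):
        r = m.baseline(Trace([1.0, 2, 3, 4], 0.1), Region(0, 4))
        assert r.mean == pytest.approx(2.5)

    def test_gaussian_noise_sd(self, rng):
        tr = Trace(rng.normal(0, 1, 10 ** 5), 0.1)
        r = m.baseline(tr, Region(0, 10 ** 5))
        assert r.sd == pytest.approx(1.0, abs=0.02)


class TestPeak:
    def test_sine_up(self, sine10):
        base, pk = _measure_sine(sine10)
        assert pk.value == pytest.approx(10.0, abs=10 * 2 * math.pi * 1e-4)

    def test_down_on_negated_sine(self, sine10):
        neg = sine10.with_samples(-sine10.samples)
        base = m.baseline(neg, Region(0, 1))
        pk = m.peak(neg, base, Region(0, len(neg)), "down")
        assert pk.value == pytest.approx(-10.0, abs=0.01)

    def test_moving_average_oracle(self):
        tr = Trace([0.0, 0, 9, 0, 0], 0.1)
        base = m.baseline(tr, Region(0, 1))
        pk = m.peak(tr, base, Region(0, 5), "up", n_average=3)
        assert pk.value == pytest.approx(3.0)
        assert pk.index == 2

    def test_even_n_average_rejected(self):
        tr = Trace([0.0, 1, 0], 0.1)
        base = m.baseline(tr, Region(0, 1))
        with pytest.raises(ValueError):
            m.peak(tr, base, Region(0, 3), "up", n_average=2)


class TestRiseTime:
    def test_sine_phase(self, sine10):
        base, pk = _measure_sine(sine10)
        rise = m.rise_time(sine10, base, pk)
        expect = (math.asin(0.8) - math.asin(0.2)) / (2 * math.pi)
        assert rise.duration == pytest.approx(expect, abs=1e-4)

    def test_linear_ramp_closed_form(self):
        n = 1001
        tr = Trace(np.linspace(0, 5.0, n), 1.0 / (n - 1))
        base = m.baseline(tr, Region(0, 1))
        pk = m.peak(tr, base, Region(0, n), "up")
        rise = m.rise_time(tr, base, pk)
        assert rise.duration == pytest.approx(0.6, abs=2e-3)

    def test_amplitude_scale_invariance(self, sine10):
        base, pk = _measure_sine(sine10)
        d1 = m.rise_time(sine10, base, pk).duration
        big = sine10.with_samples(10 * sine10.samples)
        base2, pk2 = _measure_sine(big)
        d2 = m.rise_time(big, base2, pk2).duration
        assert d1 == pytest.approx(d2, rel=1e-12)


class TestHalfDuration:
    def test_sine_phase(self, sine10):
        base, pk = _measure_sine(sine10)
        half = m.half_duration(sine10, base, pk)
        expect = 2 * (math.asin(1.0) - math.asin(0.5)) / (2 * math.pi)
        assert half.width == pytest.approx(expect, abs=1e-4)

    def test_triangle(self):
        up = np.linspace(0, 1, 501)
        tr = Trace(np.concatenate([up, up[-2::-1]]), 0.001)
        base = m.baseline(tr, Region(0, 1))
        pk = m.peak(tr, base, Region(0, len(tr)), "up")
        half = m.half_duration(tr, base, pk)
        assert half.width == pytest.approx(0.5, abs=2e-3)

    def test_gaussian_fwhm(self):
        sigma = 2.0
        tr = syn.gen_gaussian_pulse(1.0, 10.0, sigma, 4000, 0.005)
        base = m.baseline(tr, Region(0, 10))
        pk = m.peak(tr, base, Region(0, 4000), "up")
        half = m.half_duration(tr, base, pk)
        assert half.width == pytest.approx(2 * sigma * math.sqrt(2 * math.log(2)),
                                           abs=0.01)

    def test_missing_crossing_raises(self):
        tr = Trace(np.linspace(0, 1, 100), 0.01)  # never comes back down
        base = m.baseline(tr, Region(0, 1))
        pk = m.peak(tr, base, Region(0, 100), "up")
        with pytest.raises(MeasurementUndefinedError):
            m.half_duration(tr, base, pk)


class TestMaxSlope:
    def test_ramp_any_window(self):
        tr = Trace(3.0 * 0.01 * np.arange(1000), 0.01)
        for w in (0.01, 0.05, 0.2):
            assert m.max_slope(tr, Region(0, 1000), w).value == pytest.approx(3.0)

    def test_window_dt_equals_adjacent_differences(self, rng):
        tr = Trace(rng.normal(0, 1, 500), 0.02)
        got = m.max_slope(tr, Region(0, 500), window_ms=0.02).value
        brute = np.max(np.diff(tr.samples)) / 0.02
        assert got == brute  # exact equality, same arithmetic

    def test_window_rounding_rule(self):
        assert m.slope_window_samples(0.005) == 10
        assert m.slope_window_samples(0.05) == 1
        assert m.slope_window_samples(0.2) == 1  # coarser than the window


class TestThresholdCrossing:
    def test_ramp_examples(self):
        tr = Trace(2.0 * 0.01 * np.arange(100), 0.01)
        t, v = m.threshold_crossing(tr, Region(0, 100), 1.0, window_ms=0.01)
        assert t == 0.0
        with pytest.raises(MeasurementUndefinedError):
            m.threshold_crossing(tr, Region(0, 100), 3.0, window_ms=0.01)

    def test_exponential_rise_matches_scan(self):
        tau, n, dt = 5.0, 2000, 0.01
        tr = syn.gen_monoexp(1.0, tau, 0.0, n, dt)
        rev = tr.with_samples(tr.samples[::-1].copy())
        rate = 0.05
        t, _ = m.threshold_crossing(rev, Region(0, n), rate, window_ms=dt)
        y = rev.samples
        scan = next(i for i in range(n - 1) if (y[i + 1] - y[i]) / dt >= rate)
        assert t == pytest.approx(scan * dt)


class TestFootAndLatency:
    def test_foot_closed_form(self):
        rise = m.RiseTimeResult(0.2, 0.8, 0.2, 0.8)
        tr = Trace([0.0, 1.0], 0.1)
        base = m.BaselineResult(0.0, 0.0, Region(0, 1))
        assert m.foot_time(tr, base, rise) == pytest.approx(0.0)

    def test_ramp_foot_at_onset(self):
        n = 2000
        samples = np.concatenate([np.zeros(500), np.arange(n - 500) * 0.01])
        tr = Trace(samples, 0.01)
        base = m.baseline(tr, Region(0, 400))
        pk = m.peak(tr, base, Region(0, n), "up")
        rise = m.rise_time(tr, base, pk)
        assert m.foot_time(tr, base, rise) == pytest.approx(tr.time_at(500), abs=0.01)

    def test_sigmoid_foot_before_t_low(self):
        t = 0.01 * np.arange(2000)
        tr = Trace(1.0 / (1.0 + np.exp(-(t - 10.0) / 0.5)), 0.01)
        base = m.baseline(tr, Region(0, 10))
        pk = m.peak(tr, base, Region(0, 2000), "up")
        rise = m.rise_time(tr, base, pk)
        assert m.foot_time(tr, base, rise) < rise.t_low

    def test_latency_modes(self):
        tr = syn.gen_gaussian_pulse(1.0, 5.0, 1.0, 2000, 0.01)
        cursors = {"baseline": Region(0, 10), "peak": Region(0, 2000)}
        ms1 = m.measure_all(tr, cursors, direction="up")
        shifted = tr.with_samples(np.roll(tr.samples, 150))
        ms2 = m.measure_all(shifted, cursors, direction="up")
        assert m.latency(ms1, ms1, "peak_to_peak") == 0.0
        assert m.latency(ms1, ms2, "peak_to_peak") == pytest.approx(1.5)
        lat = m.latency(ms1, ms2, "max_slope_to_foot")
        assert lat == pytest.approx(ms2.foot - ms1.slope_rise.at_time)


class TestMeasureAll:
    def test_reference_sine(self, sine10):
        ms = m.measure_all(sine10, {"baseline": Region(0, 1),
                                    "peak": Region(0, len(sine10))},
                           direction="up")
        assert ms.peak.value == pytest.approx(10.0, abs=0.01)
        assert ms.rise.duration * 2 * math.pi / math.pi == pytest.approx(0.231, abs=1e-3)
        assert ms.half.width * 2 * math.pi / math.pi == pytest.approx(0.667, abs=1e-3)

    def test_constant_trace_names_peak(self):
        tr = Trace([2.0] * 100, 0.1)
        with pytest.raises(MeasurementUndefinedError) as err:
            m.measure_all(tr, {"baseline": Region(0, 10), "peak": Region(10, 100)})
        assert err.value.measurement == "peak"

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_y_scaling_laws(self, scale):
        """Time-like results invariant, value-like results linear in y-scale."""
        tr = syn.gen_sine(10.0, 1.0, 2000, 5e-4)
        big = tr.with_samples(scale * tr.samples)
        cur = {"baseline": Region(0, 1), "peak": Region(0, 2000)}
        a = m.measure_all(tr, cur, direction="up")
        b = m.measure_all(big, cur, direction="up")
        assert b.rise.duration == pytest.approx(a.rise.duration, rel=1e-9)
        assert b.half.width == pytest.approx(a.half.width, rel=1e-9)
        assert b.peak.value == pytest.approx(scale * a.peak.value, rel=1e-9)
        assert b.slope_rise.value == pytest.approx(scale * a.slope_rise.value,
                                                   rel=1e-9)
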