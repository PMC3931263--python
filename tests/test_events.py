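import numpy as np
import pytest

from patchkit import events as ev
from patchkit import synthetic as syn
from patchkit.core import Region, Trace
from patchkit.errors import DetectionError


def _template(dt=0.05):
    k = syn.epsc_kernel(0.2, 2.5, dt)
    return ev.Template(k / np.max(k), dt)


def _embed(template, positions, scales, n, offset=0.0):
    r = np.full(n, offset)
    for pos, s in zip(positions, scales):
        w = template.waveform
        r[pos:pos + w.size] += s * w
    return Trace(r, template.dt, "pA")


class TestTemplate:
    def test_normalization_enforced(self):
        with pytest.raises(ValueError):
            ev.Template(np.array([0.0, 0.5, 0.2]), 0.05)

    def test_must_start_at_baseline(self):
        with pytest.raises(ValueError):
            ev.Template(np.array([0.5, 1.0, 0.1]), 0.05)

    def test_make_template_recovers_kernel(self, rng):
        dt = 0.05
        k = syn.epsc_kernel(0.2, 2.5, dt)
        kernel = -k / np.max(k)
        n = 40000
        r = np.zeros(n)  # clean repeated events on a flat baseline
        positions = np.arange(1000, n - k.size - 1000, 4000)
        for p in positions:
            r[p:p + k.size] += kernel
        tpl = ev.make_template(Trace(r, dt, "pA"), k_sd=5, pre_ms=1.0, post_ms=10.0)
        # compare aligned at the peaks, both normalized to unit extremum
        got = tpl.waveform
        i_g, i_r = tpl.peak_offset, int(np.argmax(k))
        span = min(i_g, i_r), min(got.size - i_g, k.size - i_r)
        a = got[i_g - span[0]:i_g + span[1]]
        b = (k / np.max(k))[i_r - span[0]:i_r + span[1]]
        rms = np.sqrt(np.mean((a - b) ** 2))
        assert rms < 0.02

    def test_no_candidates_raises(self, rng):
        tr = Trace(rng.normal(0, 1, 5000), 0.05, "pA")
        with pytest.raises(DetectionError):
            ev.make_template(tr, k_sd=50)


class TestSlidingFit:
    def test_exact_scale_and_offset(self):
        tpl = _template()
        tr = _embed(tpl, [500], [3.0], 2000, offset=7.0)
        m, c, chi2 = ev.sliding_linear_fit(tr, tpl)
        assert m[500] == pytest.approx(3.0, rel=1e-9)
        assert c[500] == pytest.approx(7.0, rel=1e-9)
        assert chi2[500] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_one_at_match(self):
        tpl = _template()
        tr = _embed(tpl, [500], [3.0], 2000, offset=7.0)
        crit = ev.template_criterion(tr, tpl, "correlation")
        assert crit.values[500] == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_window_regression_oracle(self, rng):
        tpl = _template()
        tr = Trace(rng.normal(0, 1, 2000), tpl.dt, "pA")
        for method in ("scale", "correlation"):
            crit = ev.template_criterion(tr, tpl, method)
            p, n = tpl.waveform, tpl.n
            for s in (0, 371, 1000, 2000 - n):
                y = tr.samples[s:s + n]
                mm, cc = np.polyfit(p, y, 1)
                chi2 = np.sum((y - mm * p - cc) ** 2)
                if method == "scale":
                    expect = mm / np.sqrt(chi2 / (n - 1))
                else:
                    expect = abs(np.corrcoef(p, y)[0, 1])
                assert crit.values[s] == pytest.approx(expect, rel=1e-8)

    def test_correlation_affine_invariance(self, rng):
        tpl = _template()
        tr = Trace(rng.normal(0, 1, 3000), tpl.dt, "pA")
        c1 = ev.template_criterion(tr, tpl, "correlation").values
        tr2 = Trace(2.5 * tr.samples + 11.0, tpl.dt, "pA")
        c2 = ev.template_criterion(tr2, tpl, "correlation").values
        sl = slice(0, 3000 - tpl.n + 1)
        assert np.allclose(c1[sl], c2[sl], atol=1e-9)

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError):
            flat = ev.Template(np.full(50, 1.0), 0.05)


class TestDeconvolution:
    def test_delta_recovery(self):
        tpl = _template()
        tr = _embed(tpl, [800], [1.0], 4000)
        crit = ev.deconvolution_criterion(tr, tpl, noise_sd=1e-3)
        assert abs(int(np.argmax(crit.values)) - 800) <= 1

    def test_two_overlapping_events_resolved(self):
        tpl = _template()
        sep = int(round(5.0 / tpl.dt))
        tr = _embed(tpl, [800, 800 + sep], [1.0, 1.0], 4000)
        crit = ev.deconvolution_criterion(tr, tpl, noise_sd=1e-3)
        v = crit.values
        peaks = sorted(np.argsort(v)[-2:])
        assert abs(peaks[0] - 800) <= 1 and abs(peaks[1] - 800 - sep) <= 1

    def test_linearity(self, rng):
        tpl = _template()
        r1 = Trace(rng.normal(0, 1, 2048), tpl.dt, "pA")
        r2 = Trace(rng.normal(0, 1, 2048), tpl.dt, "pA")
        both = Trace(r1.samples + r2.samples, tpl.dt, "pA")
        c1 = ev.deconvolution_criterion(r1, tpl, noise_sd=1.0).values
        c2 = ev.deconvolution_criterion(r2, tpl, noise_sd=1.0).values
        cb = ev.deconvolution_criterion(both, tpl, noise_sd=1.0).values
        assert np.allclose(cb, c1 + c2, atol=1e-8 * np.max(np.abs(cb)))


class TestHistogramSD:
    def test_pure_gaussian(self, rng):
        sd = ev.histogram_gaussian_sd(rng.normal(0, 2, 400_000))
        assert sd == pytest.approx(2.0, abs=0.05)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ev.histogram_gaussian_sd(np.zeros(5000))

    def test_outlier_robustness(self, rng):
        x = rng.normal(0, 1, 100_000)
        x[:1000] = rng.normal(0, 20, 1000)
        sd = ev.histogram_gaussian_sd(x)
        assert sd == pytest.approx(1.0, rel=0.10)


class TestDetectEvents:
    def _crit(self, values, sd=1.0, peak_offset=0):
        v = np.asarray(values, float)
        return ev.CriterionTrace(v, "deconvolution", 0.05, 0.0, sd,
                                 Region(0, v.size), peak_offset)

    def test_all_below_threshold(self):
        out = ev.detect_events(self._crit(np.zeros(100)), 4.0, 1.0)
        assert len(out) == 0

    def test_single_peak(self):
        v = np.zeros(100)
        v[40:44] = [5, 8, 7, 5]
        out = ev.detect_events(self._crit(v, peak_offset=3), 4.0, 1.0)
        assert len(out) == 1
        assert out.events[0].onset_index == 41
        assert out.events[0].peak_index == 44
        assert out.events[0].criterion_value == 8

    def test_nearby_runs_merged_keeping_larger(self):
        v = np.zeros(300)
        v[100] = 6.0
        v[110] = 9.0  # 0.5 ms later at dt=0.05
        out = ev.detect_events(self._crit(v), 4.0, min_interval_ms=1.0)
        assert len(out) == 1
        assert out.events[0].onset_index == 110

    def test_train_count_within_poisson_error(self, short_train, kernel_template):
        trace, truth = short_train
        crit = ev.deconvolution_criterion(trace, kernel_template)
        out = ev.detect_events(crit, 4.0, min_interval_ms=0.5, direction="down")
        expect = len(truth)
        assert abs(len(out) - expect) <= 3 * np.sqrt(expect)


class TestEvaluateDetection:
    def _events(self, idx, dt=0.05):
        return ev.EventList([ev.Event(i, i, 1.0) for i in sorted(idx)], dt)

    def test_perfect(self):
        truth = np.array([10.0, 20.0, 30.0])
        events = self._events([200, 400, 600])
        err = ev.evaluate_detection(events, truth, 2.0)
        assert err.false_positives == 0 and err.false_negatives == 0

    def test_one_extra_detection(self):
        truth = np.array([10.0, 20.0])
        events = self._events([200, 400, 900])
        err = ev.evaluate_detection(events, truth, 2.0)
        assert err.false_positives == 1 and err.false_negatives == 0

    def test_jitter_within_tolerance(self, rng):
        truth = np.sort(rng.uniform(0, 1000, 50))
        truth = truth[np.diff(np.concatenate([[-10], truth])) > 5]
        jitter = rng.uniform(-1.9, 1.9, truth.size)
        events = self._events(np.round((truth + jitter) / 0.05).astype(int))
        err = ev.evaluate_detection(events, truth, 2.0)
        assert err.false_positives == 0 and err.false_negatives == 0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            ev.evaluate_detection(self._events([1]), np.array([0.0]), -1.0)
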