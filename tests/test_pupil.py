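"""Pupil preprocessing: blink interpolation, QC, derivative, shift,
TR resampling."""

import numpy as np
import pytest

from pupilbold import (PupilTrace, compute_derivative, interpolate_blinks,
                       preprocess_pupil, qc_invalid_fraction,
                       resample_to_volumes, shift_trace)
from pupilbold.pupil import UnrecoverableTraceError


def make_trace(diameter, rate=250.0, valid=None):
    diameter = np.asarray(diameter, dtype=float)
    if valid is None:
        valid = np.ones(diameter.size, dtype=bool)
    return PupilTrace(diameter=diameter, valid=valid, rate=rate)


class TestInterpolateBlinks:
    def test_widened_window_replaced(self):
        # blink flagged over [1.0, 1.2) s: the replaced window must extend
        # 100 ms before onset and 400 ms after offset, i.e. [0.9, 1.6) s
        n = 500
        # strictly convex trace: the interpolating chord differs from the
        # original at every interior sample of the replaced window
        d = (np.arange(n, dtype=float) - 250.0) ** 2 / 1000.0
        valid = np.ones(n, dtype=bool)
        valid[250:300] = False
        out = interpolate_blinks(make_trace(d, valid=valid))
        changed = np.flatnonzero(out.diameter != d)
        assert changed.min() == 225 and changed.max() == 399
        assert changed.size == 400 - 225
        assert out.valid.all()

    def test_clean_trace_unchanged(self):
        t = make_trace(np.sin(np.arange(100)))
        out = interpolate_blinks(t)
        np.testing.assert_array_equal(out.diameter, t.diameter)

    def test_linear_between_flanks(self):
        # 10-sample widened gap between values 4.0 and 6.0 -> straight line
        d = np.full(40, 4.0)
        d[20:] = 6.0
        valid = np.ones(40, dtype=bool)
        valid[18:21] = False   # widened by 1 pre + 4 post at rate 10
        out = interpolate_blinks(make_trace(d, rate=10.0, valid=valid))
        gap = slice(17, 25)    # 18-1 .. 20+4 inclusive
        expected = np.linspace(4.0, 6.0, 25 - 17 + 2)[1:-1]
        np.testing.assert_allclose(out.diameter[gap], expected)

    def test_boundary_blink_holds_nearest(self):
        d = np.concatenate([[0.0, 0.0], np.full(8, 5.0)])
        valid = np.ones(10, dtype=bool)
        valid[:2] = False
        out = interpolate_blinks(make_trace(d, rate=10.0, valid=valid))
        assert out.diameter[0] == out.diameter[1] == 5.0

    def test_all_invalid_raises(self):
        with pytest.raises(UnrecoverableTraceError):
            interpolate_blinks(make_trace(np.zeros(10),
                                          valid=np.zeros(10, dtype=bool)))


class TestQCInvalidFraction:
    @pytest.mark.parametrize("n_invalid, include", [
        (0, True),           # clean session always kept
        (25, True),          # exactly 25%: strict inequality, kept
        (30, False),         # >25% invalid: excluded
    ])
    def test_threshold_rule(self, n_invalid, include):
        valid = np.ones(100, dtype=bool)
        valid[:n_invalid] = False
        frac, keep = qc_invalid_fraction(make_trace(np.ones(100),
                                                    valid=valid))
        assert frac == pytest.approx(n_invalid / 100)
        assert keep is include

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            qc_invalid_fraction(make_trace(np.array([])))


class TestDerivative:
    def test_constant_is_zero(self):
        out = compute_derivative(make_trace(np.full(50, 3.3)))
        np.testing.assert_allclose(out.diameter, 0.0)

    def test_linear_ramp(self):
        t = np.arange(100) / 250.0
        out = compute_derivative(make_trace(5.0 + 0.5 * t))
        np.testing.assert_allclose(out.diameter, 0.5, rtol=1e-9)

    def test_sine_amplitude(self):
        # d/dt sin(2*pi*f*t) has amplitude 2*pi*f
        t = np.arange(5000) / 250.0
        out = compute_derivative(make_trace(np.sin(2 * np.pi * 0.1 * t)))
        assert np.max(np.abs(out.diameter)) == pytest.approx(
            2 * np.pi * 0.1, rel=1e-3)
        # spot-check an interior sample against the analytic derivative
        mid = 2000
        assert out.diameter[mid] == pytest.approx(
            2 * np.pi * 0.1 * np.cos(2 * np.pi * 0.1 * (t[mid] + 0.5 / 250)),
            rel=1e-3)


class TestShift:
    def test_zero_shift_identity(self):
        t = make_trace(np.arange(20.0), rate=10.0)
        np.testing.assert_array_equal(shift_trace(t, 0.0).diameter,
                                      t.diameter)

    def test_impulse_moves_earlier(self):
        d = np.zeros(250 * 20)
        d[250 * 10] = 1.0
        out = shift_trace(make_trace(d), 1.0)
        assert out.diameter[250 * 9] == 1.0
        assert out.diameter[250 * 10] == 0.0

    def test_trailing_hold(self):
        t = make_trace(np.arange(10.0), rate=10.0)
        out = shift_trace(t, 0.3)
        np.testing.assert_array_equal(out.diameter[-3:], 9.0)

    def test_excessive_shift_raises(self):
        with pytest.raises(ValueError):
            shift_trace(make_trace(np.ones(10), rate=10.0), 2.0)


class TestResample:
    def test_session_gives_150_volumes(self):
        t = make_trace(np.random.default_rng(0).standard_normal(75000) + 5)
        reg = resample_to_volumes(t, tr=2.0, n_volumes=150)
        assert reg.values.size == 150

    def test_identical_bin_untouched(self):
        t = make_trace(np.full(100, 7.0), rate=10.0)
        reg = resample_to_volumes(t, tr=2.0, n_volumes=5)
        np.testing.assert_allclose(reg.values, 7.0)
        assert reg.recomputed_fraction == 0.0

    def test_outlier_dropped_and_mean_recomputed(self, rng):
        inliers = rng.normal(5.0, 0.1, 499)
        bin_samples = np.concatenate([inliers, [50.0]])
        rng.shuffle(bin_samples)
        t = make_trace(bin_samples, rate=250.0)
        reg = resample_to_volumes(t, tr=2.0, n_volumes=1)
        # oracle: brute-force recomputation over the constructed bin
        m, s = bin_samples.mean(), bin_samples.std()
        keep = np.abs(bin_samples - m) <= 3 * s
        assert reg.values[0] == pytest.approx(bin_samples[keep].mean())
        assert reg.values[0] == pytest.approx(
            bin_samples[bin_samples < 40].mean())
        assert reg.recomputed_fraction == pytest.approx(1 / 500)

    def test_recomputed_fraction_monotone_in_k(self, rng):
        t = make_trace(rng.standard_normal(3000) + 5)
        fracs = [resample_to_volumes(t, 2.0, 6, outlier_k=k)
                 .recomputed_fraction for k in (1.0, 2.0, 3.0, 4.0)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            resample_to_volumes(make_trace(np.ones(100)), 2.0, 150)


class TestPipeline:
    def test_output_length_and_provenance(self, default_session):
        res = preprocess_pupil(default_session.pupil, 2.0, 150, shift=1.0)
        for variant, reg in res["regressors"].items():
            assert reg.n_volumes == 150
            assert reg.shift_applied == 1.0
            assert reg.pipeline[0] == "interpolate"
            assert reg.pipeline[-1] == "resample"
        assert "derivative" in res["regressors"]["derivative"].pipeline
        assert res["qc"]["include"]

    def test_regressors_demeaned(self, default_session):
        res = preprocess_pupil(default_session.pupil, 2.0, 150)
        for reg in res["regressors"].values():
            assert abs(reg.values.mean()) < 1e-10

    def test_shift_recovered_by_crosscorrelation(self, default_session):
        # shifting then cross-correlating against the unshifted regressor
        # must peak at the applied shift
        from pupilbold import cross_correlate_lags
        unshifted = preprocess_pupil(default_session.pupil, 2.0, 150,
                                     shift=0.0)["regressors"]["size"].values
        shifted = preprocess_pupil(default_session.pupil, 2.0, 150,
                                   shift=2.0)["regressors"]["size"].values
        cc = cross_correlate_lags(shifted, unshifted, 2.0)
        assert cc.peak_lag == -2.0
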