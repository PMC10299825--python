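"""Blind point-process HRF estimation: cleaning, event detection, basis
fitting, Wiener deconvolution and the per-ROI estimator."""

import numpy as np
import pytest

from pupilbold import (EstimationImpossibleError, EventTrain, canonical_hrf,
                       clean_signal, detect_pseudo_events, estimate_roi_hrf,
                       fit_event_hrf, kernel_at_tr,
                       simulate_point_process_bold, wiener_recover_neural)


class TestCleanSignal:
    def test_nuisance_removed(self, rng):
        nuis = rng.standard_normal((150, 5))
        y = nuis @ rng.standard_normal(5) + 0.01 * rng.standard_normal(150)
        out = clean_signal(y, nuis, 2.0)
        # residual variance a tiny fraction of the input's
        X = np.hstack([np.ones((150, 1)), nuis])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert resid.var() < 0.05 * y.var()

    def test_orthogonal_signal_preserved(self, rng):
        n = 300
        nuis = rng.standard_normal((n, 5))
        embedded = rng.standard_normal(n)
        # make it exactly orthogonal to the nuisance block + intercept
        X = np.hstack([np.ones((n, 1)), nuis])
        embedded -= X @ np.linalg.lstsq(X, embedded, rcond=None)[0]
        y = embedded + nuis @ rng.standard_normal(5)
        out = clean_signal(y, nuis, 2.0)
        assert np.corrcoef(out.values, embedded)[0, 1] > 0.95

    def test_zscored(self, default_session):
        out = clean_signal(default_session.bold[:, 0], None, 2.0)
        assert abs(out.values.mean()) < 1e-8
        assert out.values.std() == pytest.approx(1.0, abs=1e-8)


class TestDetectPseudoEvents:
    def test_upward_crossings(self):
        series = np.array([0, 0, 2, 2, 0, 0, 1.5, 0], dtype=float)
        ev = detect_pseudo_events(series, k=1.0)
        np.testing.assert_array_equal(ev.onsets, [2, 6])

    def test_subthreshold_raises(self):
        with pytest.raises(EstimationImpossibleError):
            detect_pseudo_events(np.zeros(50), k=1.0)

    def test_two_sided_adds_negative_events(self):
        series = np.array([0, 2, 0, -2, 0], dtype=float)
        one = detect_pseudo_events(series, k=1.0)
        two = detect_pseudo_events(series, k=1.0, two_sided=True)
        assert one.n_events == 1
        assert two.n_events == 2
        np.testing.assert_array_equal(two.event_signs(), [1.0, -1.0])

    def test_event_count_non_increasing_in_k(self, default_session):
        clean = clean_signal(default_session.bold[:, 0], None, 2.0)
        counts = []
        for k in (0.5, 1.0, 1.5, 2.0):
            try:
                counts.append(detect_pseudo_events(clean, k=k).n_events)
            except EstimationImpossibleError:
                counts.append(0)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_detections_near_true_events(self):
        """Detected onsets sit within one volume of a true event once the
        systematic neural-to-BOLD detection delay is removed."""
        kern = kernel_at_tr(5.0, 2.0)
        hits = []
        for seed in range(10):
            y, onsets = simulate_point_process_bold(
                300, 2.0, kern, rate_per_min=6, noise_sd=0.2,
                rng=np.random.default_rng(seed))
            y = (y - y.mean()) / y.std()
            ev = detect_pseudo_events(y, k=1.0)
            est = fit_event_hrf(y, ev, 2.0, lag_search=range(0, 5))
            true = np.asarray(onsets)
            for d in ev.onsets - est.onset_shift:
                hits.append(np.min(np.abs(true - d)) <= 1)
        assert np.mean(hits) >= 0.8


class TestFitEventHRF:
    def test_noiseless_self_consistency(self):
        """With the true event train and no noise the basis reproduces the
        generating kernel: TTP within one fine-grid neighbourhood, R² ~ 1."""
        kern = kernel_at_tr(5.0, 2.0)
        true_peak = canonical_hrf(5.0, 0.01).peak_time
        y, onsets = simulate_point_process_bold(
            300, 2.0, kern, rate_per_min=4, noise_sd=0.0,
            rng=np.random.default_rng(1))
        est = fit_event_hrf(y, EventTrain(np.asarray(onsets), 1.0), 2.0)
        assert est.ttp == pytest.approx(true_peak, abs=0.2)
        assert est.fit_r2 > 0.99

    def test_off_basis_kernel_within_1s(self):
        # a p1=3 kernel sits in the basis span only via the derivatives
        kern = kernel_at_tr(3.0, 2.0)
        true_peak = canonical_hrf(3.0, 0.01).peak_time
        y, onsets = simulate_point_process_bold(
            300, 2.0, kern, rate_per_min=4, noise_sd=0.0,
            rng=np.random.default_rng(2))
        est = fit_event_hrf(y, EventTrain(np.asarray(onsets), 1.0), 2.0)
        assert est.ttp == pytest.approx(true_peak, abs=1.0)

    def test_linearity(self):
        kern = kernel_at_tr(5.0, 2.0)
        y, onsets = simulate_point_process_bold(
            200, 2.0, kern, noise_sd=0.1, rng=np.random.default_rng(3))
        ev = EventTrain(np.asarray(onsets), 1.0)
        a = fit_event_hrf(y, ev, 2.0)
        b = fit_event_hrf(2.0 * y, ev, 2.0)
        np.testing.assert_allclose(b.basis_betas, 2.0 * a.basis_betas,
                                   rtol=1e-8)
        assert b.ttp == a.ttp


class TestWiener:
    def test_circular_identity_at_small_lambda(self):
        kern = kernel_at_tr(5.0, 2.0)
        x = np.random.default_rng(2).standard_normal(200)
        y = np.fft.irfft(np.fft.rfft(x) * np.fft.rfft(kern.samples, 200),
                         200)
        xhat = wiener_recover_neural(y, kern.samples, 1e-12)
        assert np.corrcoef(xhat, x)[0, 1] > 0.99

    def test_unit_impulse_kernel_is_identity(self, rng):
        y = rng.standard_normal(64)
        out = wiener_recover_neural(y, np.array([1.0]), 1e-12)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_lambda_suppresses_high_frequencies(self, rng):
        from scipy.signal import periodogram
        kern = kernel_at_tr(5.0, 2.0)
        y, _ = simulate_point_process_bold(300, 2.0, kern, noise_sd=0.2,
                                           rng=rng)
        hf_power = []
        for lam in (1e-4, 1.0):
            xhat = wiener_recover_neural(y, kern.samples, lam)
            f, p = periodogram(xhat, fs=0.5)
            hf_power.append(p[f > 0.15].sum())
        assert hf_power[1] < hf_power[0]

    def test_nonpositive_lambda_raises(self):
        with pytest.raises(ValueError):
            wiener_recover_neural(np.ones(10), np.array([1.0]), 0.0)


class TestEstimateRoiHRF:
    def _bold_pair(self, p1, seed, n=150):
        kern = kernel_at_tr(p1, 2.0)
        rng = np.random.default_rng(seed)
        return [simulate_point_process_bold(n, 2.0, kern, noise_sd=0.2,
                                            rng=rng)[0] for _ in range(2)]

    def test_single_session_supported(self):
        bolds = self._bold_pair(5.0, 4)
        est = estimate_roi_hrf(bolds[:1], [None], 2.0)
        assert est.n_events >= 1

    def test_identical_sessions_match_single(self):
        bolds = self._bold_pair(5.0, 5)
        same = [bolds[0], bolds[0].copy()]
        est2 = estimate_roi_hrf(same, [None, None], 2.0)
        est1 = estimate_roi_hrf(same[:1], [None], 2.0)
        assert est2.ttp == pytest.approx(est1.ttp, abs=1e-9)

    def test_session_order_invariance(self):
        bolds = self._bold_pair(5.0, 6)
        a = estimate_roi_hrf(bolds, [None, None], 2.0)
        b = estimate_roi_hrf(bolds[::-1], [None, None], 2.0)
        assert a.ttp == pytest.approx(b.ttp, abs=0.5)

    def test_boundary_guard_drops_seam_events(self):
        bolds = self._bold_pair(5.0, 7)
        est = estimate_roi_hrf(bolds, [None, None], 2.0)
        clean = np.concatenate(
            [clean_signal(b, None, 2.0).values for b in bolds])
        all_events = detect_pseudo_events(clean, k=1.0)
        guard = 16
        n1 = bolds[0].size
        in_guard = np.sum(((all_events.onsets >= n1 - guard)
                           & (all_events.onsets < n1))
                          | (all_events.onsets >= 2 * n1 - guard))
        assert est.n_events == all_events.n_events - in_guard
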