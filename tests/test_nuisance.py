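"""Cardiac/respiratory phase regressors, slow physiological regressors and
the 33-column nuisance design."""

import numpy as np
import pytest

from pupilbold import (PhysioRecording, SimulationConfig,
                       assemble_nuisance_design, build_nuisance_design,
                       cardiac_phase, detect_cardiac_peaks,
                       phase_fourier_regressors, respiratory_phase,
                       simulate_physio, simulate_session,
                       slow_physio_regressors)


def metronome_recording(duration=300.0, rate=50.0, bpm=60.0,
                        resp_hz=0.3, noise=0.0, seed=0):
    """Noise-free (or nearly) pulse/belt traces with known beat times."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * rate)) / rate
    peaks = np.arange(0.5, duration, 60.0 / bpm)
    pulse = np.zeros_like(t)
    for pk in peaks:
        lo, hi = int((pk - 0.2) * rate), int((pk + 0.2) * rate)
        pulse[max(0, lo):hi] += np.exp(-0.5 * ((t[max(0, lo):hi] - pk)
                                               / 0.03) ** 2)
    resp = np.sin(2 * np.pi * resp_hz * t)
    if noise:
        pulse = pulse + noise * rng.standard_normal(t.size)
        resp = resp + noise * rng.standard_normal(t.size)
    rec = PhysioRecording(pulse=pulse, resp=resp, rate_pulse=rate,
                         rate_resp=rate)
    return rec, peaks


class TestCardiacPeaks:
    def test_60bpm_count(self):
        rec, peaks = metronome_recording()
        detected = detect_cardiac_peaks(rec.pulse, rec.rate_pulse)
        assert abs(detected.size - 300) <= 2

    def test_detected_within_one_sample_of_truth(self):
        rec, peaks = metronome_recording()
        detected = detect_cardiac_peaks(rec.pulse, rec.rate_pulse)
        for d in detected:
            assert np.min(np.abs(peaks - d)) <= 1.0 / rec.rate_pulse + 1e-9

    def test_simulated_physio_peaks_recovered(self):
        cfg = SimulationConfig(seed=3)
        rec, truth = simulate_physio(cfg)
        detected = detect_cardiac_peaks(rec.pulse, rec.rate_pulse)
        assert abs(detected.size - truth.size) <= 2

    def test_flatline_raises(self):
        with pytest.raises(ValueError):
            detect_cardiac_peaks(np.zeros(1000), 50.0)


class TestCardiacPhase:
    peaks = np.arange(0.0, 10.0, 1.0)

    def test_zero_at_peak(self):
        assert cardiac_phase(np.array([3.0]), self.peaks)[0] == \
            pytest.approx(0.0)

    def test_pi_at_midpoint(self):
        assert cardiac_phase(np.array([3.5]), self.peaks)[0] == \
            pytest.approx(np.pi)

    def test_quarter_cycle(self):
        assert cardiac_phase(np.array([0.25]), self.peaks)[0] == \
            pytest.approx(np.pi / 2)


class TestRespiratoryPhase:
    def test_monotone_within_half_breath(self):
        t = np.arange(0, 60, 0.02)
        ph = respiratory_phase(np.sin(2 * np.pi * 0.3 * t), 50.0)
        rising = ph[135:195]       # one rising limb, trough to peak
        assert np.all(np.diff(rising) >= 0)

    def test_extremes_near_pi(self):
        t = np.arange(0, 60, 0.02)
        resp = np.sin(2 * np.pi * 0.3 * t)
        ph = respiratory_phase(resp, 50.0)
        assert np.max(np.abs(ph[np.abs(resp) > 0.999])) > 0.95 * np.pi

    def test_affine_invariance(self):
        t = np.arange(0, 60, 0.02)
        resp = np.sin(2 * np.pi * 0.3 * t)
        a = respiratory_phase(resp, 50.0)
        b = respiratory_phase(3.5 * resp + 100.0, 50.0)
        # rank-based, so invariant up to float rounding re-ordering ties
        np.testing.assert_allclose(a, b, atol=0.02)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            respiratory_phase(np.ones(100), 50.0)


class TestFourierRegressors:
    def test_order5_gives_10_columns(self):
        cols = phase_fourier_regressors(np.linspace(0, 2 * np.pi, 150))
        assert cols.shape == (150, 10)

    def test_constant_zero_phase(self):
        cols = phase_fourier_regressors(np.zeros(20))
        np.testing.assert_allclose(cols[:, 0::2], 0.0)   # sines
        np.testing.assert_allclose(cols[:, 1::2], 1.0)   # cosines

    def test_near_orthogonal_for_uniform_phase(self, rng):
        phase = rng.uniform(0, 2 * np.pi, 20000)
        cols = phase_fourier_regressors(phase)
        gram = cols.T @ cols / cols.shape[0]
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 0.03

    def test_bounded(self, rng):
        cols = phase_fourier_regressors(rng.uniform(-np.pi, np.pi, 500))
        assert np.all(np.abs(cols) <= 1.0)


class TestSlowRegressors:
    def test_metronomic_heart_rate(self):
        rec, peaks = metronome_recording()
        slow = slow_physio_regressors(rec, peaks, 150, 2.0)
        np.testing.assert_allclose(slow[:, 0], 1.0, atol=1e-6)   # hr_freq
        np.testing.assert_allclose(slow[:, 1], 0.0, atol=1e-6)   # hrv

    def test_resp_freq_and_rvt(self):
        rec, peaks = metronome_recording(resp_hz=0.3)
        slow = slow_physio_regressors(rec, peaks, 150, 2.0)
        # 18 breaths/min sinusoid -> 0.3 Hz within one crossing quantum
        assert np.median(slow[:, 3]) == pytest.approx(0.3, abs=0.05)
        # constant-amplitude breathing -> constant rvt
        interior = slow[5:-5, 5]
        assert np.ptp(interior) / np.median(interior) < 0.15

    def test_rvt_scales_with_amplitude(self):
        rec, peaks = metronome_recording()
        rec2 = PhysioRecording(pulse=rec.pulse, resp=2.0 * rec.resp,
                               rate_pulse=rec.rate_pulse,
                               rate_resp=rec.rate_resp)
        a = slow_physio_regressors(rec, peaks, 150, 2.0)
        b = slow_physio_regressors(rec2, peaks, 150, 2.0)
        np.testing.assert_allclose(b[:, 5], 2.0 * a[:, 5], rtol=1e-6)


class TestAssembly:
    def _blocks(self, rng, n=150):
        motion = rng.standard_normal((n, 6))
        cardiac = phase_fourier_regressors(rng.uniform(0, 2 * np.pi, n))
        resp = phase_fourier_regressors(rng.uniform(0, 2 * np.pi, n))
        slow = rng.standard_normal((n, 6))
        vent = rng.standard_normal(n)
        return motion, cardiac, resp, slow, vent

    def test_full_assembly_is_33_columns(self, rng):
        design = assemble_nuisance_design(*self._blocks(rng))
        assert design.n_columns == 33
        assert len(set(design.labels)) == 33
        assert "ventricle" in design.labels

    def test_retroicor_block_is_26_columns(self, rng):
        motion, cardiac, resp, slow, _ = self._blocks(rng)
        # RETROICOR proper: 10 cardiac + 10 respiratory + 6 slow regressors
        assert cardiac.shape[1] + resp.shape[1] + slow.shape[1] == 26

    def test_no_ventricle_gives_32(self, rng):
        motion, cardiac, resp, slow, _ = self._blocks(rng)
        design = assemble_nuisance_design(motion, cardiac, resp, slow, None)
        assert design.n_columns == 32
        assert "ventricle" not in design.labels

    def test_columns_demeaned(self, rng):
        design = assemble_nuisance_design(*self._blocks(rng))
        np.testing.assert_allclose(design.matrix.mean(axis=0), 0.0,
                                   atol=1e-12)

    def test_collinear_raises_with_labels(self, rng):
        motion, cardiac, resp, slow, vent = self._blocks(rng)
        motion[:, 5] = 2.0 * motion[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            assemble_nuisance_design(motion, cardiac, resp, slow, vent)


class TestEndToEnd:
    def test_full_design_from_session(self, default_session):
        ses = default_session
        design = build_nuisance_design(ses.physio, ses.motion, ses.ventricle,
                                       150, 2.0)
        assert design.n_columns == 33
        assert np.all(np.isfinite(design.matrix))

    def test_design_removes_physio_bleed(self):
        """Regressing out the design kills >=90% of the power at the aliased
        cardiac and respiratory frequencies."""
        from scipy.signal import periodogram
        cfg = SimulationConfig(coupling_mode="none", physio_bleed=1.0, seed=8)
        ses = simulate_session(cfg)
        design = build_nuisance_design(ses.physio, ses.motion, ses.ventricle,
                                       150, 2.0)
        y = ses.bold[:, 0]
        X = np.hstack([np.ones((150, 1)), design.matrix])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        f, p_raw = periodogram(y - y.mean(), fs=0.5)
        _, p_res = periodogram(resid, fs=0.5)
        for f_alias in (abs(cfg.heart_rate / 60 - 2 * 0.5),
                        abs(cfg.resp_rate / 60 - 0.5)):
            i = np.argmin(np.abs(f - f_alias))
            window = slice(max(0, i - 1), i + 2)
            assert p_res[window].sum() < 0.1 * p_raw[window].sum()
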