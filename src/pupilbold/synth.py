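"""Synthetic resting-state sessions with known pupil-BOLD coupling.

Generates everything the analysis consumes — a 250-Hz pupil trace with blink
gaps, cardiac pulse and respiratory belt traces, six motion parameters, a
ventricle noise series and ROI-average BOLD at TR resolution — with the
statistical structure the pipeline assumes and a recorded ground truth.

The slow pupil signal is band-limited Gaussian noise (4th-order Butterworth
band-pass, default 0.04–0.1 Hz, applied forward-backward), standardised to
unit variance: arousal-linked pupil fluctuations at rest concentrate in this
band, and a filtered-noise model asserts nothing beyond the band itself.
ROI BOLD is built from the volume-binned pupil signal via a configurable
transfer: a pure lag on the TR grid (``mode="lag"``), convolution with a
double-gamma HRF of known time-to-peak (``mode="hrf"``), or no coupling at
all (``mode="none"``).  Physiological "bleed" adds aliased cardiac and
respiratory sinusoids, phase-locked to the simulated traces, so the
nuisance model has something real to remove.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .hrf import HRFKernel, kernel_at_tr
from .nuisance import PhysioRecording
from .pupil import PupilTrace

PHYSIO_RATE = 50.0  # Hz; pulse-oximeter / belt sampling
BLINK_FLOOR = 0.2   # "diameter" recorded during a blink gap
PUPIL_BASELINE = 5.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic session.

    Defaults mirror a 5-min resting-state acquisition: TR = 2 s (150
    volumes), pupil sampled at 250 Hz, slow pupil power in 0.04–0.1 Hz,
    cardiac ~65 beats/min, respiration ~18 breaths/min, ~12 blinks/min,
    unit coupling gain with BOLD noise SD 0.5 relative to the unit-variance
    neural signal.
    """

    duration: float = 300.0
    pupil_rate: float = 250.0
    tr: float = 2.0
    n_rois: int = 3
    coupling_mode: str = "lag"          # {"lag", "hrf", "none"}
    coupling_lag: float = 0.0           # seconds, multiple of tr
    coupling_ttp: float = 2.0           # seconds (delay-of-response p1)
    coupling_gain: float = 1.0
    bold_noise_sd: float = 0.5
    physio_bleed: float = 0.2
    blink_rate: float = 12.0            # events/minute
    osc_band: tuple[float, float] = (0.04, 0.1)
    heart_rate: float = 65.0            # beats/minute
    resp_rate: float = 18.0             # breaths/minute
    seed: int = 0

    def __post_init__(self) -> None:
        n_vol = self.duration / self.tr
        if abs(n_vol - round(n_vol)) > 1e-9:
            raise ValueError("duration must be an integer number of TRs")
        spv = self.pupil_rate * self.tr
        if abs(spv - round(spv)) > 1e-9:
            raise ValueError("pupil_rate x tr must be an integer")
        nyq_vol = 0.5 / self.tr
        lo, hi = self.osc_band
        if not 0 < lo < hi <= nyq_vol:
            raise ValueError(f"osc_band must lie within (0, {nyq_vol}] Hz")
        if self.coupling_mode not in ("lag", "hrf", "none"):
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        lag_vol = self.coupling_lag / self.tr
        if abs(lag_vol - round(lag_vol)) > 1e-9:
            raise ValueError("coupling_lag must be a multiple of tr")
        if self.heart_rate <= 0 or self.resp_rate <= 0:
            raise ValueError("heart_rate and resp_rate must be positive")
        if self.heart_rate / 60.0 >= PHYSIO_RATE / 2:
            raise ValueError("heart_rate at or above the pulse-trace Nyquist")
        if self.resp_rate / 60.0 >= PHYSIO_RATE / 2:
            raise ValueError("resp_rate at or above the belt-trace Nyquist")

    @property
    def n_volumes(self) -> int:
        return int(round(self.duration / self.tr))

    @property
    def n_pupil_samples(self) -> int:
        return int(round(self.duration * self.pupil_rate))


@dataclass
class GroundTruth:
    """What the generator injected, recorded before noise is added."""

    coupling_mode: str
    true_lag: float | None
    true_ttp: float | None          # delay-of-response parameter p1
    true_ttp_peak: float | None     # the injected kernel's sampled argmax, s
    neural_signal: np.ndarray       # unit-variance pupil-linked signal at TR
    event_onsets: list[float] = field(default_factory=list)
    coupled_roi_ids: list[int] = field(default_factory=list)


@dataclass
class SyntheticSession:
    session_id: str
    config: SimulationConfig
    pupil: PupilTrace
    pupil_smooth: np.ndarray        # pre-blink 250-Hz signal (ground truth)
    physio: PhysioRecording
    cardiac_peak_times: np.ndarray  # ground truth
    motion: np.ndarray              # volumes x 6
    bold: np.ndarray                # volumes x n_rois
    ventricle: np.ndarray           # volumes
    truth: GroundTruth


def _slow_band_signal(n: int, rate: float, band: tuple[float, float],
                      rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band`` (zero-phase)."""
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def simulate_pupil(cfg: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[PupilTrace, np.ndarray]:
    """Pupil trace with blink gaps; returns ``(trace, smooth_signal)``.

    The smooth signal (baseline + band-limited slow fluctuations) is the
    ground truth; blinks are Poisson with uniform 100–400 ms gaps, during
    which the recorded diameter collapses to a floor value and the validity
    flag drops.  Samples outside blink windows equal the smooth signal
    exactly.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_pupil_samples
    smooth = PUPIL_BASELINE + _slow_band_signal(n, cfg.pupil_rate,
                                                cfg.osc_band, rng)
    diameter = smooth.copy()
    valid = np.ones(n, dtype=bool)
    if cfg.blink_rate > 0:
        n_blinks = rng.poisson(cfg.blink_rate * cfg.duration / 60.0)
        onsets = np.sort(rng.uniform(0, cfg.duration, n_blinks))
        durations = rng.uniform(0.1, 0.4, n_blinks)
        for onset, dur in zip(onsets, durations):
            i0 = int(onset * cfg.pupil_rate)
            i1 = min(n, int((onset + dur) * cfg.pupil_rate))
            diameter[i0:i1] = BLINK_FLOOR
            valid[i0:i1] = False
    trace = PupilTrace(diameter=diameter, valid=valid, rate=cfg.pupil_rate)
    return trace, smooth


def simulate_physio(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[PhysioRecording, np.ndarray]:
    """Pulse and belt traces; returns ``(recording, cardiac_peak_times)``.

    Beats follow the configured rate with ~3% inter-beat jitter; the pulse
    trace is a train of 60-ms Gaussian systolic bumps over low-amplitude
    noise.  The belt is a sinusoid at the breathing rate with slow (0.01 Hz)
    amplitude modulation and additive noise.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    mean_ibi = 60.0 / cfg.heart_rate
    n_beats = int(np.ceil(cfg.duration / mean_ibi)) + 2
    ibis = mean_ibi * (1.0 + 0.03 * rng.standard_normal(n_beats))
    ibis = np.clip(ibis, 0.4 * mean_ibi, 1.6 * mean_ibi)
    peaks = np.cumsum(ibis) - ibis[0] + 0.5 * mean_ibi
    peaks = peaks[peaks < cfg.duration]
    t = np.arange(int(cfg.duration * PHYSIO_RATE)) / PHYSIO_RATE
    pulse = np.zeros_like(t)
    for pk in peaks:
        lo = max(0, int((pk - 0.2) * PHYSIO_RATE))
        hi = min(t.size, int((pk + 0.2) * PHYSIO_RATE))
        pulse[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - pk) / 0.03) ** 2)
    pulse += 0.02 * rng.standard_normal(t.size)
    f_resp = cfg.resp_rate / 60.0
    amp = 1.0 + 0.2 * np.sin(2 * np.pi * 0.01 * t
                             + rng.uniform(0, 2 * np.pi))
    resp = amp * np.sin(2 * np.pi * f_resp * t + rng.uniform(0, 2 * np.pi))
    resp += 0.02 * rng.standard_normal(t.size)
    rec = PhysioRecording(pulse=pulse, resp=resp, rate_pulse=PHYSIO_RATE,
                          rate_resp=PHYSIO_RATE)
    return rec, peaks


def bin_to_volumes(signal: np.ndarray, rate: float, tr: float,
                   n_volumes: int) -> np.ndarray:
    """Bin-average a high-rate signal onto the volume grid."""
    per_bin = int(round(rate * tr))
    return signal[: n_volumes * per_bin].reshape(n_volumes, per_bin).mean(axis=1)


def _physio_bleed(cfg: SimulationConfig, peak_times: np.ndarray,
                  rng: np.random.Generator, n_volumes: int) -> np.ndarray:
    """Aliased cardiac + respiratory sinusoids at the volume midpoints.

    Phase-locked to the simulated beats (via the cumulative cardiac phase)
    and to the belt fundamental, so first-order RETROICOR regressors can
    remove them.
    """
    from .nuisance import cardiac_phase
    mids = (np.arange(n_volumes) + 0.5) * cfg.tr
    card = np.sin(cardiac_phase(mids, peak_times) + rng.uniform(0, 2 * np.pi))
    f_resp = cfg.resp_rate / 60.0
    resp = np.sin(2 * np.pi * f_resp * mids + rng.uniform(0, 2 * np.pi))
    return card + resp


def simulate_bold_from_pupil(pupil_smooth_tr: np.ndarray,
                             cfg: SimulationConfig,
                             peak_times: np.ndarray | None = None,
                             rng: np.random.Generator | None = None
                             ) -> tuple[np.ndarray, GroundTruth]:
    """ROI BOLD from the volume-binned pupil-linked neural signal.

    ``mode="lag"``: ``BOLD(t) = gain·neural(t − lag) + noise`` (the lag is a
    TR multiple; leading samples hold the first value, which the lagged
    cross-correlation's shrinking overlap excludes, so the noise-free argmax
    is exact at ``−lag``).  ``mode="hrf"``: the neural signal convolved with
    a double-gamma kernel of the configured time-to-peak.  ``mode="none"``:
    noise plus optional physiological bleed only.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    n_vol = cfg.n_volumes
    neural = np.asarray(pupil_smooth_tr, dtype=float)
    if neural.size != n_vol:
        raise ValueError(f"pupil signal has {neural.size} points; "
                         f"expected {n_vol}")
    neural = (neural - neural.mean()) / neural.std()
    true_lag = true_ttp = true_peak = None
    if cfg.coupling_mode == "lag":
        true_lag = cfg.coupling_lag
        d = int(round(cfg.coupling_lag / cfg.tr))
        signal = np.empty(n_vol)
        if d >= 0:
            signal[d:] = neural[: n_vol - d] if d else neural
            signal[:d] = neural[0]
        else:
            signal[:d] = neural[-d:]
            signal[d:] = neural[-1]
        signal = cfg.coupling_gain * signal
    elif cfg.coupling_mode == "hrf":
        kern = kernel_at_tr(cfg.coupling_ttp, cfg.tr)
        true_ttp = cfg.coupling_ttp
        fine = kernel_at_tr(cfg.coupling_ttp, 0.01)
        true_peak = fine.peak_time
        signal = cfg.coupling_gain * np.convolve(neural, kern.samples)[:n_vol]
    else:
        signal = np.zeros(n_vol)
    bold = np.empty((n_vol, cfg.n_rois))
    coupled = [] if cfg.coupling_mode == "none" else list(range(cfg.n_rois))
    for r in range(cfg.n_rois):
        roi = signal + cfg.bold_noise_sd * rng.standard_normal(n_vol)
        if cfg.physio_bleed > 0 and peak_times is not None:
            roi = roi + cfg.physio_bleed * _physio_bleed(cfg, peak_times,
                                                         rng, n_vol)
        bold[:, r] = roi
    truth = GroundTruth(coupling_mode=cfg.coupling_mode, true_lag=true_lag,
                        true_ttp=true_ttp, true_ttp_peak=true_peak,
                        neural_signal=neural, coupled_roi_ids=coupled)
    return bold, truth


def simulate_point_process_bold(n_volumes: int, tr: float,
                                kernel: HRFKernel,
                                rate_per_min: float = 6.0,
                                noise_sd: float = 0.2,
                                rng: np.random.Generator | None = None
                                ) -> tuple[np.ndarray, list[int]]:
    """BOLD from a Poisson train of delta events convolved with an HRF.

    Ground truth for the blind deconvolution path: returns the noisy series
    and the event onset volume indices (strictly increasing).
    """
    rng = rng or np.random.default_rng(0)
    if abs(kernel.dt - tr) > 1e-9:
        raise ValueError("kernel must be sampled at the TR")
    p_event = rate_per_min * tr / 60.0
    onsets = np.flatnonzero(rng.random(n_volumes) < p_event)
    train = np.zeros(n_volumes)
    train[onsets] = 1.0
    y = np.convolve(train, kernel.samples)[:n_volumes]
    y = y + noise_sd * rng.standard_normal(n_volumes)
    return y, list(onsets)


def simulate_motion(cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Six slow random-walk motion parameters (mm / radians), demeaned."""
    rng = rng or np.random.default_rng(cfg.seed + 3)
    steps = 0.01 * rng.standard_normal((cfg.n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    return walk - walk.mean(axis=0, keepdims=True)


def simulate_session(cfg: SimulationConfig,
                     session_id: str = "sub-01_ses-01") -> SyntheticSession:
    """One complete session; ``cfg.seed`` fully determines the output."""
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(5)
    trace, smooth = simulate_pupil(cfg, streams[0])
    physio, peaks = simulate_physio(cfg, streams[1])
    smooth_tr = bin_to_volumes(smooth, cfg.pupil_rate, cfg.tr, cfg.n_volumes)
    bold, truth = simulate_bold_from_pupil(smooth_tr, cfg, peaks, streams[2])
    motion = simulate_motion(cfg, streams[3])
    vent_rng = streams[4]
    ventricle = vent_rng.standard_normal(cfg.n_volumes)
    if cfg.physio_bleed > 0:
        ventricle = ventricle + cfg.physio_bleed * _physio_bleed(
            cfg, peaks, vent_rng, cfg.n_volumes)
    return SyntheticSession(session_id=session_id, config=cfg, pupil=trace,
                            pupil_smooth=smooth, physio=physio,
                            cardiac_peak_times=peaks, motion=motion,
                            bold=bold, ventricle=ventricle, truth=truth)


def simulate_study(n_participants: int, n_sessions: int,
                   cfg: SimulationConfig, ttp_jitter_sd: float = 0.0,
                   out_dir=None) -> list[list[SyntheticSession]]:
    """A cohort of synthetic participants (1 or 2 sessions each).

    Per-participant coupling time-to-peaks may be jittered around the
    configured value (``ttp_jitter_sd``, seconds, truncated to [1, 6]).
    Returns sessions grouped by participant; if ``out_dir`` is given the
    study is also written to disk with a manifest (see :mod:`pupilbold.io`).
    """
    if n_sessions not in (1, 2):
        raise ValueError("n_sessions must be 1 or 2")
    root = np.random.default_rng(cfg.seed)
    study: list[list[SyntheticSession]] = []
    for p in range(n_participants):
        p_cfg = cfg
        if ttp_jitter_sd > 0 and cfg.coupling_mode == "hrf":
            ttp = float(np.clip(cfg.coupling_ttp
                                + ttp_jitter_sd * root.standard_normal(),
                                1.0, 6.0))
            p_cfg = replace(cfg, coupling_ttp=ttp)
        sessions = []
        for s in range(n_sessions):
            seed = int(root.integers(0, 2 ** 31 - 1))
            s_cfg = replace(p_cfg, seed=seed)
            sessions.append(simulate_session(
                s_cfg, session_id=f"sub-{p + 1:02d}_ses-{s + 1:02d}"))
        study.append(sessions)
    if out_dir is not None:
        from .io import write_study
        write_study(study, out_dir)
    return study
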