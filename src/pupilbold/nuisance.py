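"""Movement + physiological noise model (33 regressors).

Six motion parameters, a fifth-order Fourier expansion of cardiac and
respiratory phase (RETROICOR; 10 columns each), six slow physiological
regressors (heart-rate frequency, heart-rate variability, raw belt signal,
respiratory frequency, respiratory amplitude, respiration volume per time),
and one ventricle signal column.  Phases are evaluated at each volume's
temporal midpoint.  Window lengths for the slow regressors (6 s cardiac,
12 s respiratory) follow the conventions of the RETROICOR/RVT literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import rankdata

CARDIAC_WINDOW_S = 6.0
RESP_WINDOW_S = 12.0
#: physiologically plausible inter-beat interval range (seconds)
IBI_RANGE = (0.33, 2.0)
REFRACTORY_S = 0.25

SLOW_LABELS = ("hr_freq", "hrv", "belt_raw", "resp_freq", "resp_amp", "rvt")


@dataclass
class PhysioRecording:
    """Cardiac pulse and respiratory belt traces covering the scan."""

    pulse: np.ndarray
    resp: np.ndarray
    rate_pulse: float
    rate_resp: float
    cardiac_peaks: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.pulse = np.asarray(self.pulse, dtype=float)
        self.resp = np.asarray(self.resp, dtype=float)
        self.cardiac_peaks = np.asarray(self.cardiac_peaks, dtype=float)
        if self.rate_pulse <= 0 or self.rate_resp <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def duration(self) -> float:
        return self.pulse.size / self.rate_pulse


@dataclass
class NuisanceDesign:
    """Labeled per-volume nuisance regressor matrix (demeaned columns)."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.labels):
            raise ValueError("label count must match column count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def detect_cardiac_peaks(pulse: np.ndarray, rate: float) -> np.ndarray:
    """Cardiac peak times (s) via thresholded local maxima.

    Peaks must exceed an adaptive threshold halfway between the median and
    the 95th percentile, and respect a 0.25-s refractory period.  Inter-beat
    intervals outside the plausible [0.33, 2] s range trigger a warning but
    are kept (downstream windows are robust to isolated misses).
    """
    pulse = np.asarray(pulse, dtype=float)
    if rate < 10:
        raise ValueError("pulse sampling rate must be at least 10 Hz")
    if np.ptp(pulse) < 1e-12:
        raise ValueError("flat-line pulse trace: no peaks detectable")
    lo, hi = np.median(pulse), np.percentile(pulse, 95)
    height = lo + 0.5 * (hi - lo)
    idx, _ = find_peaks(pulse, height=height,
                        distance=max(1, int(round(REFRACTORY_S * rate))))
    if idx.size < 2:
        raise ValueError("fewer than two cardiac peaks: phase undefined")
    times = idx / rate
    ibis = np.diff(times)
    odd = (ibis < IBI_RANGE[0]) | (ibis > IBI_RANGE[1])
    if odd.any():
        warnings.warn(f"{int(odd.sum())} inter-beat interval(s) outside "
                      f"{IBI_RANGE} s")
    return times


def cardiac_phase(t: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Linear cardiac phase in [0, 2π): 0 at each peak, 2π at the next.

    Times outside the detected peak range reuse the nearest inter-beat
    interval (extrapolation with the edge beat period).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 2:
        raise ValueError("need at least two peaks")
    # index of the interval [peaks[i], peaks[i+1]) containing t
    i = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, peaks.size - 2)
    phase = 2 * np.pi * (t - peaks[i]) / (peaks[i + 1] - peaks[i])
    return np.mod(phase, 2 * np.pi)


def respiratory_phase(resp: np.ndarray, rate: float,
                      smooth_s: float = 0.5) -> np.ndarray:
    """Amplitude-histogram-equalised respiratory phase in (-π, π].

    The belt amplitude's empirical rank maps to [0, π]; the sign of the
    (lightly smoothed) derivative distinguishes inhalation from exhalation.
    Rank-based, hence invariant to affine rescaling of the belt signal.
    """
    resp = np.asarray(resp, dtype=float)
    if np.ptp(resp) < 1e-12:
        raise ValueError("constant respiratory trace: phase undefined")
    from scipy.ndimage import uniform_filter1d
    n_smooth = max(1, int(round(smooth_s * rate)))
    smooth = uniform_filter1d(resp, n_smooth, mode="nearest")
    mag = np.pi * (rankdata(resp) - 0.5) / resp.size
    drv = np.gradient(smooth)
    sign = np.where(drv >= 0, 1.0, -1.0)
    return sign * mag


def phase_fourier_regressors(phase: np.ndarray, order: int = 5) -> np.ndarray:
    """sin(mφ), cos(mφ) for m = 1..order → ``2·order`` columns."""
    phase = np.asarray(phase, dtype=float)
    cols = []
    for m in range(1, order + 1):
        cols.append(np.sin(m * phase))
        cols.append(np.cos(m * phase))
    return np.column_stack(cols)


def _window_mask(times: np.ndarray, center: float, width: float) -> np.ndarray:
    return (times >= center - width / 2) & (times <= center + width / 2)


def slow_physio_regressors(recording: PhysioRecording, peaks: np.ndarray,
                           n_volumes: int, tr: float) -> np.ndarray:
    """Six slow physiological regressors on the volume grid.

    Per volume midpoint: heart-rate frequency (1/mean IBI in a 6-s window),
    heart-rate variability (SD of those IBIs), mean belt amplitude in the TR
    bin, respiratory frequency (mean-crossing count in a 12-s window),
    respiratory amplitude (max−min belt excursion in that window), and RVT
    (excursion divided by the breath period, i.e. excursion × frequency).
    Windows with no usable beats or breaths carry the previous value forward.
    """
    peaks = np.asarray(peaks, dtype=float)
    mids = (np.arange(n_volumes) + 0.5) * tr
    ibi_t = peaks[1:]
    ibis = np.diff(peaks)
    t_resp = np.arange(recording.resp.size) / recording.rate_resp
    resp = recording.resp
    resp_centered = resp - resp.mean()

    out = np.zeros((n_volumes, 6))
    prev = np.array([np.nan] * 6)
    for v, mid in enumerate(mids):
        m = _window_mask(ibi_t, mid, CARDIAC_WINDOW_S)
        if m.any():
            hr = 1.0 / ibis[m].mean()
            hrv = float(ibis[m].std())
        else:
            hr, hrv = prev[0], prev[1]
        b = (t_resp >= v * tr) & (t_resp < (v + 1) * tr)
        belt = float(resp[b].mean()) if b.any() else prev[2]
        w = _window_mask(t_resp, mid, RESP_WINDOW_S)
        if w.any():
            seg = resp_centered[w]
            crossings = int(np.sum(np.diff(np.signbit(seg)) != 0))
            width = t_resp[w][-1] - t_resp[w][0]
            rf = crossings / 2.0 / width if width > 0 else prev[3]
            ra = float(np.ptp(resp[w]))
            rvt = ra * rf
        else:
            rf, ra, rvt = prev[3], prev[4], prev[5]
        row = np.array([hr, hrv, belt, rf, ra, rvt], dtype=float)
        if np.isnan(row).any():
            warnings.warn(f"volume {v}: empty physiological window, carrying "
                          "previous value forward")
            row = np.where(np.isnan(row), 0.0, row)
        out[v] = row
        prev = row
    return out


def assemble_nuisance_design(motion: np.ndarray, cardiac: np.ndarray,
                             resp: np.ndarray, slow: np.ndarray,
                             ventricle: np.ndarray | None) -> NuisanceDesign:
    """Concatenate, label and demean the nuisance blocks.

    Full assembly yields 33 columns (6 motion + 10 cardiac + 10 respiratory
    + 6 slow + 1 ventricle); omitting the ventricle yields 32.  A
    rank-deficient result raises with the offending labels.
    """
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    blocks = [("motion", motion,
               [f"motion_{i + 1}" for i in range(motion.shape[1])]),
              ("cardiac", cardiac,
               [f"card_{f}{m}" for m in range(1, 6) for f in ("sin", "cos")]),
              ("resp", resp,
               [f"resp_{f}{m}" for m in range(1, 6) for f in ("sin", "cos")]),
              ("slow", slow, list(SLOW_LABELS))]
    if ventricle is not None:
        blocks.append(("ventricle",
                       np.asarray(ventricle, dtype=float).reshape(-1, 1),
                       ["ventricle"]))
    n = motion.shape[0]
    cols, labels = [], []
    for name, block, block_labels in blocks:
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] != n:
            raise ValueError(f"{name} block has {block.shape[0]} rows, "
                             f"expected {n}")
        if block.shape[1] != len(block_labels):
            raise ValueError(f"{name} block has unexpected column count "
                             f"{block.shape[1]}")
        cols.append(block)
        labels.extend(block_labels)
    matrix = np.hstack(cols)
    matrix = matrix - matrix.mean(axis=0, keepdims=True)
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        # pinpoint offending columns via QR with column norms
        _, r = np.linalg.qr(matrix)
        diag = np.abs(np.diag(r))
        bad = [labels[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient nuisance design (rank {rank} of "
                         f"{matrix.shape[1]}); collinear columns: {bad}")
    return NuisanceDesign(matrix=matrix, labels=labels)


def build_nuisance_design(recording: PhysioRecording, motion: np.ndarray,
                          ventricle: np.ndarray | None, n_volumes: int,
                          tr: float, order: int = 5) -> NuisanceDesign:
    """End-to-end nuisance model from raw physio traces and motion params."""
    peaks = detect_cardiac_peaks(recording.pulse, recording.rate_pulse)
    mids = (np.arange(n_volumes) + 0.5) * tr
    cphase = cardiac_phase(mids, peaks)
    rphase_full = respiratory_phase(recording.resp, recording.rate_resp)
    ridx = np.clip((mids * recording.rate_resp).astype(int), 0,
                   recording.resp.size - 1)
    rphase = rphase_full[ridx]
    cardiac = phase_fourier_regressors(cphase, order=order)
    resp = phase_fourier_regressors(rphase, order=order)
    slow = slow_physio_regressors(recording, peaks, n_volumes, tr)
    return assemble_nuisance_design(motion, cardiac, resp, slow, ventricle)
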