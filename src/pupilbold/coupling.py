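"""The three headline pupil-BOLD coupling analyses.

1. TTP sweep — six canonical HRFs with delay-of-response 1..6 s convolved
   with both pupil variants (size, derivative), one GLM per (TTP, variant).
2. Lagged cross-correlation of the unconvolved pupil regressor with the
   cleaned BOLD series, ±8 s in 2-s steps, with optional partialing of a
   confound ROI at lag 0.
3. Welch cross-spectral density (window 10 samples, overlap 3, Hann taper).

Lag convention: ``r(ℓ) = corr(bold(t), pupil(t + ℓ))``, so negative lags
mean pupil changes precede the BOLD signal.  Every result object stores the
convention string to keep the sign from silently flipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .glm import GLMFit, pupil_coupling_tstat
from .hrf import kernel_at_tr, convolve_at_tr
from .pupil import PupilRegressor

LAG_CONVENTION = "negative lag = pupil precedes BOLD"
DEFAULT_TTP_GRID = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
MIN_OVERLAP = 10


@dataclass
class TTPSweepResult:
    """t-statistics per (variant, TTP) for one participant and ROI."""

    ttp_grid: tuple[float, ...]
    variants: tuple[str, ...]
    t_values: dict            # (variant, ttp) -> GLMFit
    errors: dict = field(default_factory=dict)

    def to_frame(self, **ids) -> pd.DataFrame:
        rows = []
        for (variant, ttp), fit in self.t_values.items():
            rows.append({**ids, "variant": variant, "ttp_s": ttp,
                         "t": fit.t_target, "dof": fit.dof,
                         "rho": fit.ar1_rho})
        return pd.DataFrame(rows)


@dataclass
class CrossCorrResult:
    lags: np.ndarray          # seconds
    r: np.ndarray
    z: np.ndarray
    convention: str = LAG_CONVENTION

    @property
    def peak_lag(self) -> float:
        return float(self.lags[int(np.argmax(self.r))])

    def to_frame(self, **ids) -> pd.DataFrame:
        return pd.DataFrame({**ids, "lag_s": self.lags, "r": self.r,
                             "z": self.z})


@dataclass
class CSDResult:
    frequencies: np.ndarray   # Hz
    cross_power: np.ndarray   # magnitude
    peak_frequency: float

    def to_frame(self, **ids) -> pd.DataFrame:
        return pd.DataFrame({**ids, "frequency_hz": self.frequencies,
                             "cross_power": self.cross_power})


def ttp_sweep(bold_sessions: list[np.ndarray],
              pupil_sessions: dict[str, list[np.ndarray]],
              nuisance_sessions: list[np.ndarray | None], tr: float,
              ttp_grid: tuple[float, ...] = DEFAULT_TTP_GRID
              ) -> TTPSweepResult:
    """One GLM per (TTP, pupil variant): 6 kernels × 2 variants = 12 cells.

    ``pupil_sessions`` maps variant name to the per-session unconvolved
    volume-locked pupil regressors.  GLM failures in individual cells are
    recorded and the sweep continues.
    """
    variants = tuple(pupil_sessions)
    t_values, errors = {}, {}
    for ttp in ttp_grid:
        kern = kernel_at_tr(ttp, tr)
        for variant in variants:
            convolved = [convolve_at_tr(np.asarray(p, dtype=float), kern, tr)
                         for p in pupil_sessions[variant]]
            try:
                t_values[(variant, float(ttp))] = pupil_coupling_tstat(
                    bold_sessions, convolved, nuisance_sessions, tr)
            except (ValueError, np.linalg.LinAlgError) as exc:
                errors[(variant, float(ttp))] = str(exc)
    return TTPSweepResult(ttp_grid=tuple(float(t) for t in ttp_grid),
                          variants=variants, t_values=t_values,
                          errors=errors)


def cross_correlate_lags(pupil: np.ndarray | PupilRegressor,
                         bold_clean: np.ndarray, tr: float,
                         max_lag: float = 8.0, step: float = 2.0
                         ) -> CrossCorrResult:
    """Pearson r at each lag over the shrinking overlap (no padding).

    ``r(ℓ) = corr(bold(t), pupil(t + ℓ))``; both series are demeaned within
    the overlapping support of each lag.  Fewer than 10 overlapping points
    raise.
    """
    p = pupil.values if isinstance(pupil, PupilRegressor) else \
        np.asarray(pupil, dtype=float)
    b = np.asarray(bold_clean, dtype=float)
    if p.size != b.size:
        raise ValueError("pupil and BOLD series must have equal length")
    n_steps = int(round(max_lag / step))
    lags = np.arange(-n_steps, n_steps + 1) * step
    rs = np.empty(lags.size)
    for i, lag in enumerate(lags):
        d = int(round(lag / tr))
        if d >= 0:
            x, y = b[: b.size - d] if d else b, p[d:]
        else:
            x, y = b[-d:], p[: p.size + d]
        if x.size < MIN_OVERLAP:
            raise ValueError(f"overlap at lag {lag} s is {x.size} < "
                             f"{MIN_OVERLAP} points")
        rs[i] = np.corrcoef(x, y)[0, 1]
    z = np.arctanh(np.clip(rs, -1 + 1e-12, 1 - 1e-12))
    return CrossCorrResult(lags=lags.astype(float), r=rs, z=z)


def _residualize(y: np.ndarray, confound: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(confound.size), confound])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation_lag0(pupil: np.ndarray, bold_target: np.ndarray,
                             bold_confound: np.ndarray
                             ) -> tuple[float, float]:
    """Lag-0 correlation before and after regressing out a confound ROI.

    Both the pupil and the target series are residualised on the confound
    (with intercept); returns ``(r_full, r_partial)``.
    """
    pupil = np.asarray(pupil, dtype=float)
    target = np.asarray(bold_target, dtype=float)
    conf = np.asarray(bold_confound, dtype=float)
    if conf.std() < 1e-12:
        raise ValueError("constant confound series")
    r_full = float(np.corrcoef(pupil, target)[0, 1])
    rp, rt = _residualize(pupil, conf), _residualize(target, conf)
    # a series collinear with the confound leaves no residual variance:
    # nothing left to correlate
    if rp.std() < 1e-9 * pupil.std() or rt.std() < 1e-9 * target.std():
        return r_full, 0.0
    r_partial = float(np.corrcoef(rp, rt)[0, 1])
    return r_full, r_partial


def cross_spectral_density(pupil: np.ndarray, bold_clean: np.ndarray,
                           tr: float, window: int = 10, overlap: int = 3,
                           nfft: int = 256) -> CSDResult:
    """Welch-averaged cross-spectral magnitude of pupil and BOLD.

    Hann-tapered segments of ``window`` samples with ``overlap`` samples of
    overlap at fs = 1/TR; the spectrum is evaluated on a zero-padded
    ``nfft``-point grid so peak frequencies resolve finer than the window's
    native resolution.  ``peak_frequency`` is the argmax over f > 0.
    """
    p = np.asarray(pupil, dtype=float)
    b = np.asarray(bold_clean, dtype=float)
    if p.size != b.size:
        raise ValueError("series lengths differ")
    if window > p.size:
        raise ValueError(f"window {window} exceeds series length {p.size}")
    freqs, pxy = sp_signal.csd(p, b, fs=1.0 / tr, window="hann",
                               nperseg=window, noverlap=overlap, nfft=nfft)
    mag = np.abs(pxy)
    pos = freqs > 0
    peak = float(freqs[pos][int(np.argmax(mag[pos]))])
    return CSDResult(frequencies=freqs, cross_power=mag, peak_frequency=peak)
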