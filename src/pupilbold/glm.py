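"""First-level GLM on ROI time series.

Discrete-cosine high-pass drift (1/128 Hz cut-off), AR(1) prewhitening
estimated from the OLS residuals (Yule–Walker, single global rho per
series), and extraction of the pupil-regressor t-statistic.  Two-session
designs are block-diagonal per session with per-session intercepts, drift
and nuisance blocks; the contrast is the unweighted mean of the per-session
pupil betas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_HIGHPASS_S = 128.0
AR1_CLAMP = 0.99


@dataclass
class GLMFit:
    betas: np.ndarray
    labels: list[str]
    residual_variance: float
    dof: int
    t_target: float
    p_target: float
    ar1_rho: float

    def beta(self, label: str) -> float:
        return float(self.betas[self.labels.index(label)])


def dct_highpass_basis(n_volumes: int, tr: float,
                       cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """Discrete cosine drift columns with periods above ``cutoff_s``.

    Column count is ``floor(2·n·tr/cutoff)`` (the SPM convention); columns
    are mutually orthogonal by construction.
    """
    if n_volumes < 4:
        raise ValueError("need at least 4 volumes")
    if cutoff_s <= 2 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    k = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    t = np.arange(n_volumes)
    cols = [np.sqrt(2.0 / n_volumes)
            * np.cos(np.pi * (2 * t + 1) * j / (2.0 * n_volumes))
            for j in range(1, k + 1)]
    return (np.column_stack(cols) if cols
            else np.empty((n_volumes, 0)))


def _ar1_rho(resid: np.ndarray) -> float:
    denom = float(resid @ resid)
    if denom <= 0:
        return 0.0
    return float(resid[1:] @ resid[:-1] / denom)


def _projection_rho_bias(X: np.ndarray) -> float:
    """Lag-1 autocorrelation a residual inherits from the projection alone.

    Projecting white noise off smooth regressors (drift, slow physiological
    columns) leaves residuals with expected lag-1 autocorrelation
    ``−tr(PL)/(n−p)`` (P the hat matrix, L the lag operator).  Subtracting
    this design-induced bias from the raw residual estimate keeps the
    prewhitened t-statistics calibrated.
    """
    q, _ = np.linalg.qr(X)
    tr_pl = float(np.sum(q[1:] * q[:-1]))
    return -tr_pl / (X.shape[0] - X.shape[1])


def _whiten(a: np.ndarray, rho: float) -> np.ndarray:
    """Exact AR(1) whitening: first row scaled by sqrt(1-rho²)."""
    a = np.atleast_2d(a.T).T if a.ndim == 1 else a
    out = np.empty_like(a, dtype=float)
    out[0] = a[0] * np.sqrt(1.0 - rho ** 2)
    out[1:] = a[1:] - rho * a[:-1]
    return out


def fit_ar1_glm(y: np.ndarray, X: np.ndarray, target_index: int,
                labels: list[str] | None = None) -> GLMFit:
    """OLS fit, AR(1) rho from the residuals, prewhitened refit.

    The t-statistic of column ``target_index`` uses ``dof = n - rank(X)``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in y or X")
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design matrix rank-deficient ({rank} < {p})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rho = _ar1_rho(y - X @ beta) - _projection_rho_bias(X)
    if abs(rho) >= AR1_CLAMP:
        warnings.warn(f"AR(1) rho {rho:.3f} clamped to ±{AR1_CLAMP}")
        rho = float(np.clip(rho, -AR1_CLAMP, AR1_CLAMP))
    yw = _whiten(y[:, None], rho)[:, 0]
    Xw = _whiten(X, rho)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    dof = n - rank
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2 * xtx_inv[target_index, target_index])
    t = float(beta[target_index] / se) if se > 0 else np.inf
    p_val = float(2 * stats.t.sf(abs(t), dof))
    return GLMFit(betas=beta,
                  labels=labels or [f"col_{i}" for i in range(p)],
                  residual_variance=sigma2, dof=dof, t_target=t,
                  p_target=p_val, ar1_rho=rho)


def _session_design(nuisance: np.ndarray | None, pupil: np.ndarray,
                    tr: float, cutoff_s: float) -> np.ndarray:
    n = pupil.size
    drift = dct_highpass_basis(n, tr, cutoff_s)
    blocks = [np.ones((n, 1)), drift]
    if nuisance is not None and nuisance.size:
        blocks.append(np.atleast_2d(np.asarray(nuisance, dtype=float)))
    blocks.append(pupil[:, None])
    return np.hstack(blocks)


def pupil_coupling_tstat(bold_sessions: list[np.ndarray],
                         pupil_sessions: list[np.ndarray],
                         nuisance_sessions: list[np.ndarray | None],
                         tr: float,
                         cutoff_s: float = DEFAULT_HIGHPASS_S) -> GLMFit:
    """t-statistic of the pupil regressor across one or two sessions.

    The design is block-diagonal per session (intercept, drift, nuisance and
    one pupil column each); the reported effect is the unweighted mean of
    the per-session pupil betas, with its standard error from the whitened
    normal equations.  Single-session input degenerates to a one-block
    design, so the two-session machinery and the single-session path agree
    by construction.
    """
    if not bold_sessions:
        raise ValueError("no sessions")
    if not (len(bold_sessions) == len(pupil_sessions)
            == len(nuisance_sessions)):
        raise ValueError("session lists must have equal length")
    designs, pupil_cols = [], []
    for bold, pup, nui in zip(bold_sessions, pupil_sessions,
                              nuisance_sessions):
        bold = np.asarray(bold, dtype=float)
        pup = np.asarray(pup, dtype=float)
        if bold.size != pup.size:
            raise ValueError("bold and pupil lengths differ within a session")
        designs.append(_session_design(nui, pup, tr, cutoff_s))
        pupil_cols.append(designs[-1].shape[1] - 1)
    n_sessions = len(designs)
    widths = [d.shape[1] for d in designs]
    n_total = sum(d.shape[0] for d in designs)
    X = np.zeros((n_total, sum(widths)))
    y = np.concatenate([np.asarray(b, dtype=float) for b in bold_sessions])
    r0 = c0 = 0
    contrast = np.zeros(sum(widths))
    for d, pc in zip(designs, pupil_cols):
        X[r0:r0 + d.shape[0], c0:c0 + d.shape[1]] = d
        contrast[c0 + pc] = 1.0 / n_sessions
        r0 += d.shape[0]
        c0 += d.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient multi-session design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rho = _ar1_rho(y - X @ beta) - _projection_rho_bias(X)
    if abs(rho) >= AR1_CLAMP:
        warnings.warn(f"AR(1) rho {rho:.3f} clamped")
        rho = float(np.clip(rho, -AR1_CLAMP, AR1_CLAMP))
    yw = _whiten(y[:, None], rho)[:, 0]
    Xw = _whiten(X, rho)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    dof = y.size - rank
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    effect = float(contrast @ beta)
    se = float(np.sqrt(sigma2 * contrast @ xtx_inv @ contrast))
    t = effect / se if se > 0 else np.inf
    p_val = float(2 * stats.t.sf(abs(t), dof))
    return GLMFit(betas=beta, labels=[f"col_{i}" for i in range(X.shape[1])],
                  residual_variance=sigma2, dof=dof, t_target=t,
                  p_target=p_val, ar1_rho=rho)
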