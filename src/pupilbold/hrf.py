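"""Double-gamma hemodynamic response function family.

The canonical HRF is the difference of two gamma densities: a positive
response lobe and a delayed undershoot.  The family is parameterised the way
SPM's ``spm_hrf`` is, and the "time-to-peak" (TTP) that analysis sweeps vary
is the delay-of-response parameter ``p1`` — *not* the kernel's analytic
argmax, which for a gamma with unit dispersion sits at ``p1 - p3`` before the
undershoot pulls it slightly earlier.  ``HRFKernel.peak_time`` always reports
the sampled argmax so the two notions stay distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import gamma as _gamma


@dataclass(frozen=True)
class HRFParams:
    """Parameters of the double-gamma kernel (SPM ordering).

    delay_response
        ``p1``, seconds — delay of the response lobe; the swept "TTP".
    delay_undershoot
        ``p2``, seconds — delay of the undershoot lobe.
    dispersion_response, dispersion_undershoot
        ``p3``/``p4``, seconds — gamma dispersions (scales).
    ratio
        ``p5`` — response-to-undershoot amplitude ratio.
    onset
        ``p6``, seconds.
    length
        ``p7``, seconds — kernel support.
    dt
        sampling step, seconds.
    """

    delay_response: float = 6.0
    delay_undershoot: float = 16.0
    dispersion_response: float = 1.0
    dispersion_undershoot: float = 1.0
    ratio: float = 6.0
    onset: float = 0.0
    length: float = 32.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        for name in ("delay_response", "delay_undershoot",
                     "dispersion_response", "dispersion_undershoot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.length <= self.delay_response:
            raise ValueError("kernel length must exceed the response delay")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class HRFKernel:
    samples: np.ndarray
    params: HRFParams
    peak_time: float

    @property
    def dt(self) -> float:
        return self.params.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.params.dt


@dataclass(frozen=True)
class BasisSet:
    """Canonical kernel plus temporal and dispersion derivatives on one grid."""

    canonical: np.ndarray
    temporal_derivative: np.ndarray
    dispersion_derivative: np.ndarray
    params: HRFParams

    @property
    def dt(self) -> float:
        return self.params.dt

    def as_matrix(self) -> np.ndarray:
        return np.column_stack(
            [self.canonical, self.temporal_derivative, self.dispersion_derivative]
        )


def _raw_double_gamma(params: HRFParams) -> np.ndarray:
    """Unnormalised difference of gamma densities on the [0, length] grid."""
    t = np.arange(0.0, params.length + params.dt / 2, params.dt) - params.onset
    pos = _gamma.pdf(t, a=params.delay_response / params.dispersion_response,
                     scale=params.dispersion_response)
    neg = _gamma.pdf(t, a=params.delay_undershoot / params.dispersion_undershoot,
                     scale=params.dispersion_undershoot)
    return pos - neg / params.ratio


def double_gamma_hrf(params: HRFParams | None = None, *,
                     normalize: str = "peak") -> HRFKernel:
    """Sample the double-gamma HRF.

    ``normalize='peak'`` rescales to unit peak (the default; GLM t-statistics
    are invariant to positive rescaling so this is cosmetic), ``'sum'`` to
    unit integral, ``'none'`` leaves the raw density difference.
    """
    params = params or HRFParams()
    h = _raw_double_gamma(params)
    peak = float(np.max(h))
    if peak <= 0:
        raise ValueError("degenerate kernel: non-positive peak")
    if normalize == "peak":
        h = h / peak
    elif normalize == "sum":
        s = float(np.sum(h) * params.dt)
        if abs(s) < 1e-12:
            raise ValueError("kernel integrates to ~0; cannot sum-normalise")
        h = h / s
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    peak_time = float(np.argmax(h) * params.dt)
    return HRFKernel(samples=h, params=params, peak_time=peak_time)


def canonical_hrf(ttp: float, dt: float = 0.1, **kwargs) -> HRFKernel:
    """Canonical kernel with the delay-of-response parameter set to ``ttp``."""
    return double_gamma_hrf(HRFParams(delay_response=ttp, dt=dt, **kwargs))


def hrf_basis_set(params: HRFParams | None = None,
                  td_shift: float = 1.0,
                  dd_step: float = 0.01) -> BasisSet:
    """Canonical HRF with temporal- and dispersion-derivative partners.

    The temporal derivative is the backward finite difference
    ``[h(t) - h(t; onset + td_shift)] / td_shift``; the dispersion derivative
    is the finite difference of ``h`` with respect to the response dispersion
    (step ``dd_step``).  All three share the canonical grid and the canonical
    lobe's peak scaling, so fitted coefficients stay comparable.
    """
    params = params or HRFParams()
    h = _raw_double_gamma(params)
    h_shift = _raw_double_gamma(replace(params, onset=params.onset + td_shift))
    td = (h - h_shift) / td_shift
    h_disp = _raw_double_gamma(
        replace(params, dispersion_response=params.dispersion_response + dd_step))
    dd = (h - h_disp) / dd_step
    scale = float(np.max(h))
    return BasisSet(canonical=h / scale, temporal_derivative=td / scale,
                    dispersion_derivative=dd / scale, params=params)


def kernel_at_tr(ttp: float, tr: float, **kwargs) -> HRFKernel:
    """Canonical kernel sampled directly on the volume (TR) grid."""
    return canonical_hrf(ttp, dt=tr, **kwargs)


def convolve_at_tr(values: np.ndarray, kernel: HRFKernel, tr: float,
                   demean: bool = True) -> np.ndarray:
    """Causal convolution of a volume-resolution regressor with an HRF.

    The kernel must already live on the TR grid; convolution is truncated to
    the regressor's length and (by default) demeaned, since the session
    intercept lives in the design matrix.
    """
    if abs(kernel.dt - tr) > 1e-9:
        raise ValueError(
            f"kernel dt {kernel.dt} does not match TR {tr}; resample first")
    values = np.asarray(values, dtype=float)
    out = np.convolve(values, kernel.samples)[: values.size]
    if demean:
        out = out - out.mean()
    return out
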