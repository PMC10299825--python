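"""Pupil preprocessing: blink interpolation, derivative, shift, TR resampling.

The pipeline order is fixed — interpolate blinks, differentiate (for the
derivative variant), shift the trace 1 s back in time to compensate the
pupil's lag behind the neural activity that drives it, then bin-average to
the fMRI volume grid with a ±3 SD within-bin outlier rule.  Each output
records the steps applied so downstream tables stay traceable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np

#: a raw session is excluded when more than this fraction of samples is invalid
INVALID_FRACTION_LIMIT = 0.25


class UnrecoverableTraceError(ValueError):
    """Raised when a pupil trace has no valid samples to interpolate from."""


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter with per-sample validity flags."""

    diameter: np.ndarray
    valid: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.diameter.shape != self.valid.shape:
            raise ValueError("diameter and valid must have the same length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.diameter.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    @property
    def invalid_fraction(self) -> float:
        if self.n_samples == 0:
            raise ValueError("empty trace")
        return float(np.mean(~self.valid))


@dataclass
class PupilRegressor:
    """Volume-locked pupil regressor (one value per fMRI volume)."""

    values: np.ndarray
    variant: str  # "size" or "derivative"
    shift_applied: float
    n_volumes: int
    recomputed_fraction: float
    pipeline: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_volumes:
            raise ValueError("regressor length must equal n_volumes")
        if not 0.0 <= self.recomputed_fraction <= 1.0:
            raise ValueError("recomputed_fraction must lie in [0, 1]")


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive invalid samples."""
    inv = ~valid
    if not inv.any():
        return []
    edges = np.flatnonzero(np.diff(inv.astype(int)))
    starts = list(edges[inv[edges + 1]] + 1)
    stops = list(edges[~inv[edges + 1]] + 1)
    if inv[0]:
        starts.insert(0, 0)
    if inv[-1]:
        stops.append(inv.size)
    return list(zip(starts, stops))


def interpolate_blinks(trace: PupilTrace, pre: float = 0.1,
                       post: float = 0.4) -> PupilTrace:
    """Replace blink gaps by linear interpolation.

    Each invalid run is widened by ``pre`` seconds before its onset and
    ``post`` seconds after its offset; the widened window is replaced by the
    straight line between the nearest flanking valid samples.  Windows that
    reach a boundary hold the nearest valid value instead.
    """
    if trace.n_samples == 0:
        raise UnrecoverableTraceError("empty trace")
    if not trace.valid.any():
        raise UnrecoverableTraceError("no valid samples to interpolate from")
    n = trace.n_samples
    n_pre = int(round(pre * trace.rate))
    n_post = int(round(post * trace.rate))
    bad = np.zeros(n, dtype=bool)
    for start, stop in _invalid_runs(trace.valid):
        bad[max(0, start - n_pre): min(n, stop + n_post)] = True
    if not bad.any():
        return replace(trace, diameter=trace.diameter.copy(),
                       valid=trace.valid.copy())
    diameter = trace.diameter.copy()
    good_idx = np.flatnonzero(~bad)
    if good_idx.size == 0:
        raise UnrecoverableTraceError(
            "widened blink windows cover the whole trace")
    bad_idx = np.flatnonzero(bad)
    # np.interp holds the boundary value outside the first/last good sample,
    # which is exactly the documented edge behaviour.
    diameter[bad_idx] = np.interp(bad_idx, good_idx, diameter[good_idx])
    return PupilTrace(diameter=diameter, valid=np.ones(n, dtype=bool),
                      rate=trace.rate)


def qc_invalid_fraction(trace: PupilTrace) -> tuple[float, bool]:
    """Raw invalid fraction and whether the session survives the >25% rule.

    Returns ``(fraction, include)``; the cut is a strict inequality, so a
    session at exactly 25% invalid is kept.
    """
    frac = trace.invalid_fraction
    return frac, frac <= INVALID_FRACTION_LIMIT


def compute_derivative(trace: PupilTrace) -> PupilTrace:
    """First-order pupil derivative in units/s (positive = dilation).

    Forward difference scaled by the sampling rate; the final value is
    repeated to preserve length.
    """
    d = np.empty_like(trace.diameter)
    d[:-1] = np.diff(trace.diameter) * trace.rate
    d[-1] = d[-2] if trace.n_samples > 1 else 0.0
    return replace(trace, diameter=d, valid=trace.valid.copy())


def shift_trace(trace: PupilTrace, shift: float = 1.0) -> PupilTrace:
    """Shift the trace ``shift`` seconds back in time.

    The sample at output index ``i`` is the input at ``i + shift·rate``: the
    pupil is moved earlier to compensate its physiological lag behind neural
    activity.  Trailing samples hold the last available value.
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    n_shift = shift * trace.rate
    if abs(n_shift - round(n_shift)) > 1e-6:
        raise ValueError("shift must be a multiple of the sampling interval")
    n_shift = int(round(n_shift))
    if n_shift >= trace.n_samples:
        raise ValueError("shift exceeds trace duration")
    if n_shift == 0:
        return replace(trace, diameter=trace.diameter.copy(),
                       valid=trace.valid.copy())
    d = np.empty_like(trace.diameter)
    d[:-n_shift] = trace.diameter[n_shift:]
    d[-n_shift:] = trace.diameter[-1]
    v = np.empty_like(trace.valid)
    v[:-n_shift] = trace.valid[n_shift:]
    v[-n_shift:] = trace.valid[-1]
    return PupilTrace(diameter=d, valid=v, rate=trace.rate)


def resample_to_volumes(trace: PupilTrace, tr: float, n_volumes: int,
                        outlier_k: float = 3.0, variant: str = "size",
                        shift_applied: float = 0.0,
                        pipeline: tuple[str, ...] = ()) -> PupilRegressor:
    """Bin-average to the volume grid with a ±k SD within-bin outlier rule.

    For each TR bin the mean and SD are computed, samples beyond
    ``mean ± outlier_k·SD`` are dropped, and the mean is recomputed from the
    survivors.  A bin whose samples are all flagged falls back to its
    original mean (with a warning).  Samples past ``n_volumes·tr`` are
    truncated to the volume grid.
    """
    per_bin = tr * trace.rate
    if abs(per_bin - round(per_bin)) > 1e-6:
        raise ValueError("tr must be a multiple of the sampling interval")
    per_bin = int(round(per_bin))
    needed = n_volumes * per_bin
    if trace.n_samples < needed:
        raise ValueError(
            f"trace has {trace.n_samples} samples; {needed} needed for "
            f"{n_volumes} volumes at TR={tr}")
    bins = trace.diameter[:needed].reshape(n_volumes, per_bin)
    means = bins.mean(axis=1)
    sds = bins.std(axis=1)
    keep = np.abs(bins - means[:, None]) <= outlier_k * sds[:, None] + 1e-12
    n_dropped = int((~keep).sum())
    empty = ~keep.any(axis=1)
    if empty.any():
        warnings.warn(f"{int(empty.sum())} bin(s) lost all samples to the "
                      "outlier rule; falling back to the original bin mean")
        keep[empty] = True
    with np.errstate(invalid="ignore"):
        values = np.where(keep, bins, 0.0).sum(axis=1) / keep.sum(axis=1)
    return PupilRegressor(values=values, variant=variant,
                          shift_applied=shift_applied, n_volumes=n_volumes,
                          recomputed_fraction=n_dropped / needed,
                          pipeline=tuple(pipeline) + ("resample",))


def preprocess_pupil(trace: PupilTrace, tr: float, n_volumes: int,
                     shift: float = 1.0, outlier_k: float = 3.0,
                     variants: tuple[str, ...] = ("size", "derivative"),
                     demean: bool = True) -> dict:
    """Full pupil pipeline: interpolate -> (derivative) -> shift -> resample.

    Returns ``{"regressors": {variant: PupilRegressor}, "qc": {...}}``.  The
    QC block carries the raw invalid fraction, the include flag of the >25%
    rule, and the recomputed fraction of the bin-outlier rule; regressors are
    demeaned per session by default (the GLM intercept absorbs the mean).
    """
    invalid_fraction, include = qc_invalid_fraction(trace)
    interp = interpolate_blinks(trace)
    regressors: dict[str, PupilRegressor] = {}
    for variant in variants:
        steps = ["interpolate"]
        t = interp
        if variant == "derivative":
            t = compute_derivative(t)
            steps.append("derivative")
        elif variant != "size":
            raise ValueError(f"unknown variant {variant!r}")
        if shift > 0:
            t = shift_trace(t, shift)
            steps.append(f"shift:{shift}")
        reg = resample_to_volumes(t, tr, n_volumes, outlier_k=outlier_k,
                                  variant=variant, shift_applied=shift,
                                  pipeline=tuple(steps))
        if demean:
            reg.values = reg.values - reg.values.mean()
        regressors[variant] = reg
    qc = {
        "invalid_fraction": invalid_fraction,
        "include": include,
        "shift_s": shift,
        "recomputed_fraction": {v: regressors[v].recomputed_fraction
                                for v in regressors},
    }
    return {"regressors": regressors, "qc": qc}
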