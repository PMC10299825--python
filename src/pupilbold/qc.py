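"""Data-quality metrics: temporal SNR, LC contrast-to-noise, and pairwise
partial correlations between arousal nuclei controlling for a pontine
reference signal."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .coupling import _residualize
from .group import fisher_z, one_sample_ttest, fdr_adjust


def temporal_snr(data) -> float:
    """Temporal SNR: mean over SD of the time series.

    A 1-D input is a single (ROI-average) series; a 2-D input is voxels ×
    time, in which case the voxelwise tSNR is averaged across voxels.
    Invariant to multiplicative rescaling; a constant series returns +inf
    with a warning.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] < 2:
        raise ValueError("need at least two time points")
    sd = x.std(axis=1, ddof=0)
    if np.any(sd == 0):
        warnings.warn("constant series: tSNR reported as +inf")
    with np.errstate(divide="ignore"):
        per_voxel = np.abs(x.mean(axis=1)) / sd
    return float(per_voxel.mean())


def lc_cnr(mean_roi_intensity: float, mean_reference_intensity: float
           ) -> float:
    """Contrast-to-noise ratio: (I_roi − I_ref) / I_ref."""
    if mean_reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    return (mean_roi_intensity - mean_reference_intensity) \
        / mean_reference_intensity


def partial_correlation_matrix(roi_series: dict[str, np.ndarray],
                               confound: np.ndarray) -> pd.DataFrame:
    """Pairwise partial correlations controlling for the confound series.

    Each pair of (cleaned, demeaned) ROI series is residualised on the
    confound with intercept and Pearson-correlated; returns a tidy frame
    with one row per unordered pair.
    """
    confound = np.asarray(confound, dtype=float)
    if confound.std() < 1e-12:
        raise ValueError("constant confound series")
    resid = {name: _residualize(np.asarray(s, dtype=float), confound)
             for name, s in roi_series.items()}
    rows = []
    for a, b in itertools.combinations(sorted(roi_series), 2):
        r = float(np.corrcoef(resid[a], resid[b])[0, 1])
        rows.append({"roi_a": a, "roi_b": b, "r_partial": r})
    return pd.DataFrame(rows)


def group_partial_correlations(per_participant: list[pd.DataFrame]
                               ) -> pd.DataFrame:
    """Group test per ROI pair: Fisher z, one-sample t, BH-FDR over pairs."""
    stacked = pd.concat(per_participant, ignore_index=True)
    stacked["z"] = fisher_z(stacked["r_partial"].to_numpy())
    rows = []
    for (a, b), grp in stacked.groupby(["roi_a", "roi_b"], sort=True):
        z = grp["z"].to_numpy()
        t, p = one_sample_ttest(z)
        rows.append({"roi_a": a, "roi_b": b, "mean_r": float(
            np.tanh(z.mean())), "mean_z": float(z.mean()), "t": t, "p": p,
            "n": z.size})
    table = pd.DataFrame(rows)
    table["p_fdr"] = fdr_adjust(table["p"].to_numpy())
    return table
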