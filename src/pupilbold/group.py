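"""Second-level (group) inference over participants.

All procedures consume per-participant summary statistics (first-level t
values or Fisher-z correlations), never concatenated time series: one-sample
t-tests against zero, Benjamini-Hochberg FDR over the configured family
(the nine ROIs for main effects, lags-within-ROI for the cross-correlation
bins), a one-way repeated-measures ANOVA for the main effect of TTP, paired
t-tests for full-vs-partial correlation comparisons, and Spearman rank
correlations for individual-difference checks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-Z transform, ``z = atanh(r)``.

    Values at or beyond ±1 are clamped to ±(1 − 1e-12) with a warning.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("correlation(s) at |r| >= 1 clamped before atanh")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def one_sample_ttest(values) -> tuple[float, float]:
    """Two-sided one-sample t-test against zero: ``(t, p)``."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two observations")
    if values.std(ddof=1) <= 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="fdr_bh")[1]


def rm_anova_main_effect(matrix) -> tuple[float, float]:
    """One-way repeated-measures ANOVA (participants × levels): ``(F, p)``.

    Participants are the blocking factor; F has (k−1, (k−1)(n−1)) degrees of
    freedom.  A matrix with zero level and residual variance is reported as
    "no effect" (F = 0, p = 1).  Missing cells raise.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise ValueError("need a complete participants x levels matrix "
                         "with >=2 of each")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = X.shape
    grand = X.mean()
    subj = X.mean(axis=1, keepdims=True)
    level = X.mean(axis=0, keepdims=True)
    ss_level = n * float(((level - grand) ** 2).sum())
    resid = X - subj - level + grand
    ss_resid = float((resid ** 2).sum())
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_resid <= 1e-300:
        if ss_level <= 1e-300:
            return 0.0, 1.0
        return np.inf, 0.0
    F = (ss_level / df1) / (ss_resid / df2)
    return float(F), float(stats.f.sf(F, df1, df2))


def paired_comparison(full_z, partial_z) -> tuple[float, float]:
    """Paired two-sided t-test of full vs partial Fisher-z values: (t, p)."""
    a = np.asarray(full_z, dtype=float)
    b = np.asarray(partial_z, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if d.std(ddof=1) <= 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank tie handling: (rho, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three observations")
    if x.std() <= 0 or y.std() <= 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def group_table(per_participant: pd.DataFrame, value_col: str,
                condition_cols: list[str],
                fdr_family: list[str] | None = None) -> pd.DataFrame:
    """One-sample t-tests per condition cell with BH-FDR over the family.

    ``per_participant`` is tidy (one row per participant × condition);
    ``fdr_family`` names the condition columns defining one FDR family
    (default: all condition columns jointly, i.e. one family per table).
    """
    rows = []
    for keys, grp in per_participant.groupby(condition_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        vals = grp[value_col].to_numpy()
        t, p = one_sample_ttest(vals)
        rows.append({**dict(zip(condition_cols, keys)),
                     "mean": float(np.mean(vals)), "t": t, "p": p,
                     "n": vals.size})
    table = pd.DataFrame(rows)
    family_cols = fdr_family if fdr_family else []
    if family_cols:
        table["p_fdr"] = np.nan
        for _, idx in table.groupby(family_cols).groups.items():
            table.loc[idx, "p_fdr"] = fdr_adjust(table.loc[idx, "p"])
    else:
        table["p_fdr"] = fdr_adjust(table["p"])
    return table
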