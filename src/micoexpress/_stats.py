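"""Shared statistical helpers used by several pipeline stages."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are left NaN and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def shannon(proportions, base: float | None = None) -> float:
    """Shannon entropy -sum p log p over nonzero proportions (nats by default)."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return np.nan
    p = p / p.sum()
    h = -np.sum(p * np.log(p))
    if base is not None:
        h /= np.log(base)
    return float(h)


def inverse_simpson(proportions) -> float:
    """Inverse Simpson index 1 / sum p^2; equals n for a uniform n-vector."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return np.nan
    p = p / p.sum()
    return float(1.0 / np.sum(p**2))


def half_min_positive(values) -> float:
    """Half the smallest strictly positive value; multiplicative pseudocount."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if v.size == 0:
        return 0.0
    return float(v.min() / 2.0)


def group_split(meta: pd.DataFrame, samples) -> tuple[list[str], list[str]]:
    """Sample id lists for (HC, PD), restricted to `samples`, order preserved."""
    samples = list(samples)
    grp = meta.loc[samples, "group"]
    hc = [s for s in samples if grp[s] == "HC"]
    pd_ = [s for s in samples if grp[s] == "PD"]
    return hc, pd_


def rank_compare(values: pd.DataFrame, meta: pd.DataFrame,
                 min_per_group: int = 3) -> pd.DataFrame:
    """Row-wise two-sided Mann-Whitney comparison of HC vs PD samples.

    Parameters
    ----------
    values
        units x samples matrix; NaN entries are dropped per row.
    meta
        sample metadata with a ``group`` column in {HC, PD}.

    Returns a table with group medians and means, log2 fold change of
    group means (PD over HC, pseudocount = half the minimum positive
    group mean across the table), Mann-Whitney p and BH q. Rows with
    fewer than `min_per_group` non-missing observations in either group
    get NaN statistics and are excluded from the FDR family.
    """
    hc, pd_ = group_split(meta, values.columns)
    if len(hc) < min_per_group or len(pd_) < min_per_group:
        raise ValueError(
            f"need >= {min_per_group} samples per group, "
            f"got HC={len(hc)}, PD={len(pd_)}"
        )
    x = values[hc].to_numpy(dtype=float)
    y = values[pd_].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean_hc = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=1)
        mean_pd = np.nanmean(np.where(np.isfinite(y), y, np.nan), axis=1)
        med_hc = np.nanmedian(x, axis=1)
        med_pd = np.nanmedian(y, axis=1)
    eps = half_min_positive(np.concatenate([mean_hc, mean_pd]))
    log2fc = np.log2((mean_pd + eps) / (mean_hc + eps))

    pvals = np.full(values.shape[0], np.nan)
    n_hc = np.isfinite(x).sum(axis=1)
    n_pd = np.isfinite(y).sum(axis=1)
    testable = (n_hc >= min_per_group) & (n_pd >= min_per_group)
    for i in np.where(testable)[0]:
        xi = x[i][np.isfinite(x[i])]
        yi = y[i][np.isfinite(y[i])]
        if np.all(xi == xi[0]) and np.all(yi == yi[0]) and xi[0] == yi[0]:
            pvals[i] = 1.0  # identical constant rows: no evidence
            continue
        pvals[i] = stats.mannwhitneyu(xi, yi, alternative="two-sided").pvalue
    out = pd.DataFrame(
        {
            "n_hc": n_hc,
            "n_pd": n_pd,
            "mean_hc": mean_hc,
            "mean_pd": mean_pd,
            "median_hc": med_hc,
            "median_pd": med_pd,
            "log2fc": log2fc,
            "p": pvals,
        },
        index=values.index,
    )
    out["q"] = bh_adjust(out["p"])
    return out


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via Student t with n-2 df."""
    if n < 3 or not np.isfinite(r):
        return np.nan
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))
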