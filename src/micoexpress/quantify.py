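"""From MG/MT counts to normalized transcriptional activity (MTA).

The central quantity is the per-gene ratio of MT TPM to MG TPM, a
proxy of transcriptional activity that corrects expression for gene
copy abundance. This module computes TPM per layer, aggregates
features to KOs, forms the ratio, filters by prevalence, and applies
the two downstream transforms: a per-feature Yeo-Johnson power
transform (network input) and the centered log-ratio (ordination
input).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.preprocessing import PowerTransformer

from .io import AlignmentError, FeatureAnnotation, GeneFeatureTable, SampleMetadata
from ._stats import group_split

logger = logging.getLogger(__name__)

RAW_RATIO = "raw_ratio"
POWER_TRANSFORMED = "power_transformed"
CLR = "clr"


@dataclass
class ActivityMatrix:
    """Normalized gene expression, features x samples.

    ``state`` tracks the transform applied: raw_ratio (MT/MG TPM),
    power_transformed (per-feature Yeo-Johnson + standardization) or
    clr (per-sample centered log-ratio). ``report`` carries bookkeeping
    such as the number of missing-coded MT>0/MG=0 entries.
    """

    values: pd.DataFrame
    state: str = RAW_RATIO
    key: str = "ko"
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids in activity matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in activity matrix")
        if self.state == RAW_RATIO:
            arr = self.values.to_numpy()
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("negative entries in raw activity ratio")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)


def tpm(table: GeneFeatureTable) -> pd.DataFrame:
    """Transcripts per million: (R_i/L_i) / sum_j(R_j/L_j) x 1e6.

    Every sample column sums to 1e6. A sample with no reads at all has
    an undefined denominator and raises.
    """
    rate = table.counts.div(table.lengths, axis=0)
    denom = rate.sum(axis=0)
    dead = denom[denom == 0]
    if len(dead):
        raise ValueError(f"all-zero counts in sample(s) {list(dead.index)}")
    return rate.div(denom, axis=1) * 1e6


def aggregate_tpm(tpm_df: pd.DataFrame, ann: FeatureAnnotation,
                  by: str | tuple[str, ...] = "ko") -> pd.DataFrame:
    """Sum feature-level TPM onto an annotation key.

    TPM is additive (shared per-sample denominator), so summing feature
    TPM onto KOs — or (taxon, KO) pairs — is exact length-corrected
    aggregation. ``by`` is "ko" or a tuple like ("genus", "ko").
    """
    ann_tab = ann.table.reindex(tpm_df.index)
    if isinstance(by, str):
        keys = [_key_series(ann_tab, ann, by, tpm_df.index)]
    else:
        keys = [_key_series(ann_tab, ann, b, tpm_df.index) for b in by]
    grouped = tpm_df.groupby(keys, sort=True).sum()
    return grouped


def _key_series(ann_tab: pd.DataFrame, ann: FeatureAnnotation, rank: str, index):
    if rank == "ko":
        s = ann_tab["ko"]
        if s.isna().any():
            missing = int(s.isna().sum())
            logger.warning("%d features without KO annotation dropped", missing)
        return s
    return ann.taxon_at(rank).reindex(index)


def mta_ratio(mt_tpm: pd.DataFrame, mg_tpm: pd.DataFrame,
              pseudocount: float = 0.0) -> ActivityMatrix:
    """MT TPM / (MG TPM + pseudocount), the transcriptional activity ratio.

    With pseudocount 0, entries where MG is zero but MT is positive are
    undefined (they indicate mapping artifacts rather than infinite
    activity) and are missing-coded; 0/0 is 0. The count of
    missing-coded entries is recorded in the report.
    """
    if not mt_tpm.index.equals(mg_tpm.index) or not mt_tpm.columns.equals(mg_tpm.columns):
        raise AlignmentError("MT and MG TPM matrices have mismatched indices")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mt = mt_tpm.to_numpy(dtype=float)
    mg = mg_tpm.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mg > 0, mt / np.where(mg > 0, mg, 1.0), np.nan)
    undefined = (mg == 0) & (mt > 0)
    ratio[(mg == 0) & (mt == 0)] = 0.0
    ratio[undefined] = np.nan
    n_undef = int(undefined.sum())
    if n_undef:
        logger.info("%d MT>0/MG=0 entries missing-coded", n_undef)
    values = pd.DataFrame(ratio, index=mt_tpm.index, columns=mt_tpm.columns)
    return ActivityMatrix(values, RAW_RATIO, report={"n_undefined": n_undef})


def prevalence_filter(act: ActivityMatrix, min_fraction: float):
    """Keep features detected (>0, non-missing) in >= ceil(f * n) samples.

    Returns (filtered ActivityMatrix, kept ids, dropped ids).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    detected = (act.values > 0) & act.values.notna()
    n_needed = math.ceil(min_fraction * act.values.shape[1])
    keep_mask = detected.sum(axis=1) >= n_needed
    kept = list(act.values.index[keep_mask])
    dropped = list(act.values.index[~keep_mask])
    if not kept:
        raise ValueError(
            f"prevalence filter at {min_fraction} removed every feature"
        )
    out = ActivityMatrix(act.values.loc[kept], act.state, act.key,
                         dict(act.report, prevalence_dropped=len(dropped)))
    return out, kept, dropped


def power_transform(act: ActivityMatrix) -> ActivityMatrix:
    """Per-feature Yeo-Johnson power transform + standardization.

    Lambda is fitted per feature by maximum likelihood; each output
    feature has mean 0 and (population) SD 1. Constant features cannot
    be standardized and are dropped with a warning. Missing entries are
    not supported here: the network input must be complete, so callers
    fill or filter missing values first.
    """
    if act.state != RAW_RATIO:
        raise ValueError(f"power_transform expects raw_ratio input, got {act.state}")
    values = act.values
    if values.isna().any().any():
        raise ValueError("power_transform requires a complete matrix (no NaN)")
    sd = values.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant features dropped before power transform",
                       int(constant.sum()))
        values = values.loc[~constant]
    pt = PowerTransformer(method="yeo-johnson", standardize=True)
    transformed = pt.fit_transform(values.to_numpy(dtype=float).T).T
    out = pd.DataFrame(transformed, index=values.index, columns=values.columns)
    if out.isna().any().any():
        raise RuntimeError("power transform produced NaN")
    return ActivityMatrix(out, POWER_TRANSFORMED, act.key,
                          dict(act.report, lambdas=pt.lambdas_.tolist()))


def clr(values: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio per sample: log(x+pc) - mean_features(log(x+pc)).

    Default pseudocount is half the smallest nonzero value of the
    matrix (multiplicative replacement); zero is allowed only when the
    matrix contains no zeros. Each sample's transformed values sum to 0.
    """
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        arr = np.where(np.isnan(arr), 0.0, arr)
    if (arr < 0).any():
        raise ValueError("CLR requires non-negative values")
    if pseudocount is None:
        positive = arr[arr > 0]
        pseudocount = positive.min() / 2.0 if positive.size else 1e-9
    if pseudocount <= 0 and (arr == 0).any():
        raise ValueError("pseudocount must be > 0 when zeros are present")
    logged = np.log(arr + pseudocount)
    centered = logged - logged.mean(axis=0, keepdims=True)
    return pd.DataFrame(centered, index=values.index, columns=values.columns)


def clr_activity(act: ActivityMatrix, pseudocount: float | None = None) -> ActivityMatrix:
    out = clr(act.values, pseudocount)
    return ActivityMatrix(out, CLR, act.key, dict(act.report))


def prevalence_summary(act: ActivityMatrix, meta: SampleMetadata) -> dict:
    """Per-feature prevalence (overall and per group) and activity summaries.

    Also counts features above the 50% and 100% prevalence thresholds
    ("shared by half / all donors").
    """
    detected = (act.values > 0) & act.values.notna()
    hc, pd_ = group_split(meta.table, act.samples)
    per_feature = pd.DataFrame(
        {
            "prevalence": detected.mean(axis=1),
            "prevalence_hc": detected[hc].mean(axis=1),
            "prevalence_pd": detected[pd_].mean(axis=1),
        }
    )
    nonzero = act.values.where(detected)
    per_feature["mean_nonzero"] = nonzero.mean(axis=1)
    per_feature["median_nonzero"] = nonzero.median(axis=1)
    per_feature["var_nonzero"] = nonzero.var(axis=1)
    n = act.values.shape[1]
    shared_half = int((detected.sum(axis=1) >= math.ceil(0.5 * n)).sum())
    shared_all = int((detected.sum(axis=1) == n).sum())
    return {
        "table": per_feature,
        "n_shared_50pct": shared_half,
        "n_shared_all": shared_all,
    }
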