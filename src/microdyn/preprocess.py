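"""Six-step feature preprocessing chain and diet-log aggregation rules.

The chain, applied in this exact order to every molecular assay:

1. log10 transform (zeros become missing — a relative-abundance zero denotes
   non-detection, and step 5 exists precisely to fill such holes);
2. robust standardization: ``(x - m) / s`` where ``m`` and ``s`` are the
   median and sample SD of the central 90% of the distribution (values
   between the 5th and 95th linear-interpolation percentiles, inclusive);
3. outlier clipping to +-5 on the standardized (robust-SD) scale;
4. removal of features present in fewer than 20 samples;
5. paired-minimum imputation: a missing (participant, timepoint) entry is set
   to the feature's minimum observed value only if the participant's
   complementary sample has a value for that feature;
6. PC batch correction: of the first five principal components of a single
   decomposition, any that explains >= 5% of the variance *and* whose sample
   scores differ by batch (two-sided Mann-Whitney p < 0.05; smallest pairwise
   p when there are more than two batches) is reconstructed and subtracted.

Dietary data goes through steps 3 and 4 only (clipping on the raw scale uses
the feature's own mean +- 5 SD, since the data is not standardized).

Diet logs are aggregated to per-period daily means after excluding days that
report < 60% or > 240% of the personal daily caloric target, or whose
unmatched-calorie fraction exceeds 20%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .containers import FeatureTable
from .exceptions import (
    DegenerateFeatureError,
    InvalidArgumentError,
    InvalidInputError,
)

# ---------------------------------------------------------------------------
# step primitives
# ---------------------------------------------------------------------------

def log10_transform(table: FeatureTable) -> FeatureTable:
    """Step 1: replace positive values by log10; zeros become missing.

    Raises :class:`InvalidInputError`, naming the first offending feature and
    sample, if any present value is negative.
    """
    vals = table.values
    neg = vals < 0
    if neg.any().any():
        feat = neg.any(axis=0).idxmax()
        samp = neg[feat].idxmax()
        raise InvalidInputError(
            f"negative value under log10 at feature {feat!r}, sample {samp!r}"
        )
    out = table.copy()
    arr = out.values.to_numpy()
    with np.errstate(divide="ignore"):
        arr = np.where(arr > 0, np.log10(np.where(arr > 0, arr, 1.0)), np.nan)
    out.values = pd.DataFrame(arr, index=vals.index, columns=vals.columns)
    return out


def central_moments(values: np.ndarray, central_fraction: float = 0.90):
    """Median and sample SD over the central part of a distribution.

    The central region holds the values between the ``(1-f)/2`` and
    ``(1+f)/2`` linear-interpolation percentiles, bounds inclusive.
    Returns ``(median, sd)``; ``sd`` uses ddof=1.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    tail = 100.0 * (1.0 - central_fraction) / 2.0
    lo, hi = np.percentile(v, [tail, 100.0 - tail])
    central = v[(v >= lo) & (v <= hi)]
    sd = central.std(ddof=1) if central.size > 1 else 0.0
    return float(np.median(central)), float(sd)


def robust_standardize(
    values: np.ndarray, central_fraction: float = 0.90
) -> np.ndarray:
    """Step 2 for one feature: ``(x - m) / s`` with central-90% moments.

    Requires at least 3 non-missing values and a nonzero central SD; raises
    :class:`DegenerateFeatureError` otherwise. NaNs pass through unchanged.
    """
    v = np.asarray(values, dtype=float)
    n_obs = (~np.isnan(v)).sum()
    if n_obs < 3:
        raise DegenerateFeatureError("need >= 3 non-missing values")
    m, s = central_moments(v, central_fraction)
    if s == 0.0 or not np.isfinite(s):
        raise DegenerateFeatureError("zero spread in the central distribution")
    return (v - m) / s


def clip_outliers(
    values: np.ndarray, k: float = 5.0, center: float = 0.0, scale: float = 1.0
) -> np.ndarray:
    """Step 3: clip to ``center +- k*scale`` (on standardized data the
    defaults make this [-5, +5] robust-SD units). ``k=inf`` is the identity.
    NaNs pass through."""
    return np.clip(values, center - k * scale, center + k * scale)


def filter_low_prevalence(
    table: FeatureTable, min_samples: int = 20
) -> tuple[FeatureTable, list[str]]:
    """Step 4: drop features with fewer than ``min_samples`` non-missing
    values. Returns the filtered table and the list of removed feature ids
    (a feature present in exactly ``min_samples`` samples is retained)."""
    counts = table.values.notna().sum(axis=0)
    keep = counts[counts >= min_samples].index
    removed = [f for f in table.values.columns if f not in set(keep)]
    return table.subset_features(keep), removed


def impute_paired_minimum(table: FeatureTable) -> tuple[FeatureTable, int]:
    """Step 5: fill a missing (participant, timepoint, feature) cell with the
    feature's minimum observed value iff the same participant's complementary
    timepoint has a value for that feature. Imputed cells are flagged in
    ``table.imputed``. Returns the new table and the number of imputed cells.
    """
    out = table.copy()
    vals = out.values
    meta = out.sample_meta
    col_min = vals.min(axis=0, skipna=True)

    pre_ids = meta.index[meta["timepoint"] == "pre"]
    post_ids = meta.index[meta["timepoint"] == "post"]
    pre_by_p = pd.Series(pre_ids, index=meta.loc[pre_ids, "participant_id"])
    post_by_p = pd.Series(post_ids, index=meta.loc[post_ids, "participant_id"])
    common = pre_by_p.index.intersection(post_by_p.index)

    n_imputed = 0
    pre_rows = pre_by_p.loc[common].to_numpy()
    post_rows = post_by_p.loc[common].to_numpy()
    pre_vals = vals.loc[pre_rows].to_numpy()
    post_vals = vals.loc[post_rows].to_numpy()
    fill = col_min.to_numpy()

    fill_pre = np.isnan(pre_vals) & ~np.isnan(post_vals)
    fill_post = np.isnan(post_vals) & ~np.isnan(pre_vals)
    if fill_pre.any():
        pre_vals[fill_pre] = np.broadcast_to(fill, pre_vals.shape)[fill_pre]
        vals.loc[pre_rows] = pre_vals
        imp = out.imputed.loc[pre_rows].to_numpy()
        imp |= fill_pre
        out.imputed.loc[pre_rows] = imp
        n_imputed += int(fill_pre.sum())
    if fill_post.any():
        post_vals[fill_post] = np.broadcast_to(fill, post_vals.shape)[fill_post]
        vals.loc[post_rows] = post_vals
        imp = out.imputed.loc[post_rows].to_numpy()
        imp |= fill_post
        out.imputed.loc[post_rows] = imp
        n_imputed += int(fill_post.sum())
    return out, n_imputed


def _batch_association_p(scores: np.ndarray, batches: np.ndarray) -> float:
    """Two-sided Mann-Whitney p for PC scores vs batch; smallest pairwise p
    when there are more than two batches (uncorrected, by design)."""
    labels = np.unique(batches)
    best = 1.0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = scores[batches == labels[i]]
            b = scores[batches == labels[j]]
            if len(a) == 0 or len(b) == 0:
                continue
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
            best = min(best, float(p))
    return best


def pc_batch_correct(
    table: FeatureTable,
    batches: np.ndarray | None = None,
    n_components: int = 5,
    var_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> tuple[FeatureTable, list[int]]:
    """Step 6: single-pass PC batch correction.

    One PCA of the mean-centered matrix (missing cells filled with the
    feature mean for the decomposition only); each of the first
    ``n_components`` components that explains at least ``var_threshold`` of
    the variance and is batch-associated (Mann-Whitney p < ``p_threshold``)
    has its reconstruction subtracted from the data. Missing cells stay
    missing. Returns the corrected table and the removed component indices.
    """
    if batches is None:
        batches = table.sample_meta["batch"].to_numpy()
    batches = np.asarray(batches)
    if len(np.unique(batches)) < 2:
        raise InvalidArgumentError("pc_batch_correct requires >= 2 batches")

    X = table.values.to_numpy(copy=True)
    missing = np.isnan(X)
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    Xf = np.where(missing, col_mean, X)

    k = int(min(n_components, Xf.shape[0] - 1, Xf.shape[1]))
    if k < 1:
        return table.copy(), []
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xf)

    removed = [
        i
        for i in range(k)
        if pca.explained_variance_ratio_[i] >= var_threshold
        and _batch_association_p(scores[:, i], batches) < p_threshold
    ]
    out = table.copy()
    if removed:
        recon = scores[:, removed] @ pca.components_[removed]
        corrected = np.where(missing, np.nan, Xf - recon)
        out.values = pd.DataFrame(
            corrected, index=table.values.index, columns=table.values.columns
        )
    return out, removed


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------

def run_preprocessing(
    table: FeatureTable,
    batches: np.ndarray | None = None,
    min_samples: int = 20,
    clip_k: float = 5.0,
    central_fraction: float = 0.90,
    pc_count: int = 5,
    pc_var: float = 0.05,
    pc_p: float = 0.05,
) -> tuple[FeatureTable, dict]:
    """Apply steps 1-6 in order, per assay, and return (table, audit log).

    Features whose assay is ``diet`` go through steps 3 and 4 only, with the
    clip bounds taken as the feature's plain mean +- ``clip_k`` SD (the data
    is not standardized on that path). Degenerate features (zero central
    spread) are flagged in the audit and left unstandardized. Batch
    correction is skipped, with a note, when fewer than two batches exist.
    """
    audit: dict = {"assays": {}}
    pieces, metas, imputed_pieces = [], [], []

    for assay in table.assays:
        sub = table.subset_features(table.features_for_assay(assay))
        log: dict = {}
        if assay == "diet":
            arr = sub.values.to_numpy(copy=True)
            mean = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1)
            sd = np.where((sd == 0) | np.isnan(sd), np.inf, sd)
            arr = np.clip(arr, mean - clip_k * sd, mean + clip_k * sd)
            sub.values = pd.DataFrame(
                arr, index=sub.values.index, columns=sub.values.columns
            )
            sub, removed = filter_low_prevalence(sub, min_samples)
            log["steps"] = ["clip", "filter"]
            log["removed_features"] = removed
        else:
            sub = log10_transform(sub)
            degenerate = []
            arr = sub.values.to_numpy(copy=True)
            for j, feat in enumerate(sub.values.columns):
                try:
                    arr[:, j] = robust_standardize(arr[:, j], central_fraction)
                except DegenerateFeatureError:
                    degenerate.append(feat)
            arr = np.where(
                np.isin(sub.values.columns, degenerate),
                arr,
                clip_outliers(arr, k=clip_k),
            )
            sub.values = pd.DataFrame(
                arr, index=sub.values.index, columns=sub.values.columns
            )
            sub, removed = filter_low_prevalence(sub, min_samples)
            sub, n_imputed = impute_paired_minimum(sub)
            b = batches if batches is not None else sub.sample_meta["batch"].to_numpy()
            if len(np.unique(np.asarray(b))) >= 2:
                sub, removed_pcs = pc_batch_correct(
                    sub, b, n_components=pc_count,
                    var_threshold=pc_var, p_threshold=pc_p,
                )
            else:
                removed_pcs = []
                log["batch_correction"] = "skipped: fewer than 2 batches"
            log["steps"] = [
                "log10", "standardize", "clip", "filter", "impute", "batch",
            ]
            log["degenerate_features"] = degenerate
            log["removed_features"] = removed
            log["n_imputed"] = n_imputed
            log["removed_components"] = removed_pcs
        audit["assays"][assay] = log
        pieces.append(sub.values)
        metas.append(sub.feature_meta)
        imputed_pieces.append(sub.imputed)

    out = FeatureTable(
        pd.concat(pieces, axis=1),
        table.sample_meta.copy(),
        pd.concat(metas, axis=0),
        pd.concat(imputed_pieces, axis=1),
    )
    return out, audit


# ---------------------------------------------------------------------------
# diet logs
# ---------------------------------------------------------------------------

def filter_diet_days(
    logs: pd.DataFrame,
    lower: float = 0.60,
    upper: float = 2.40,
    max_unmatched: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude unusual diet-log days.

    A day is excluded iff calories < ``lower`` x target, calories >
    ``upper`` x target, or unmatched_fraction > ``max_unmatched``; a day
    with a missing or non-positive caloric target is excluded with reason
    ``no-target``. Returns (retained days, exclusions with a ``reason``
    column).
    """
    target = logs["caloric_target"]
    no_target = target.isna() | (target <= 0)
    ratio = logs["calories"] / target.where(~no_target)
    low = ratio < lower
    high = ratio > upper
    unmatched = logs["unmatched_fraction"] > max_unmatched

    reason = pd.Series(pd.NA, index=logs.index, dtype="object")
    reason[unmatched] = "unmatched"
    reason[high] = "high_calories"
    reason[low] = "low_calories"
    reason[no_target] = "no-target"

    excluded_mask = reason.notna()
    exclusions = logs[excluded_mask].assign(reason=reason[excluded_mask])
    return logs[~excluded_mask].copy(), exclusions


def summarize_diet_periods(
    logs: pd.DataFrame,
    period_map: dict | None = None,
    nutrient_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Per-participant, per-period daily means of retained diet days.

    ``period_map`` optionally maps date -> period; otherwise the logs'
    ``period`` column is used. Returns one row per (participant, period)
    with the per-nutrient mean and ``n_days_retained``; a period with zero
    retained days yields missing means and a zero count.
    """
    logs = logs.copy()
    if period_map is not None:
        logs["period"] = logs["date"].map(period_map)
    if "period" not in logs.columns:
        raise InvalidArgumentError("logs need a 'period' column or a period_map")
    if nutrient_columns is None:
        skip = {"participant_id", "date", "period", "caloric_target"}
        nutrient_columns = [
            c for c in logs.columns
            if c not in skip and pd.api.types.is_numeric_dtype(logs[c])
        ]
    grouped = logs.groupby(["participant_id", "period"])
    summary = grouped[nutrient_columns].mean()
    summary["n_days_retained"] = grouped.size()
    # complete the grid so empty periods appear with 0 days and NaN means
    full = pd.MultiIndex.from_product(
        [logs["participant_id"].unique(), ["profiling", "intervention"]],
        names=["participant_id", "period"],
    )
    summary = summary.reindex(summary.index.union(full, sort=False))
    summary["n_days_retained"] = summary["n_days_retained"].fillna(0).astype(int)
    return summary.reset_index()
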