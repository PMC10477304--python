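"""Paired pre/post differential testing and multiplicity control.

The workhorse is the Wilcoxon paired signed-rank test, chosen over the
Mann-Whitney U test whenever pairing is available to preserve power; the
between-arm baseline screen uses Mann-Whitney on pre-intervention values.
Multiplicity is controlled by Bonferroni (the default across the molecular
panels) or Benjamini-Hochberg FDR (used for the low-powered cytokine panel),
both at a two-sided alpha of 0.05 with strict-inequality rejection.

The signed-rank test drops zero differences, uses midranks for tied absolute
differences, and switches from an exact null (dynamic-programming enumeration
of all 2^n sign assignments) to a tie-corrected normal approximation above
n = 25 nonzero pairs. A feature enters testing only if the tested group shows
at least 20 unique values, counting all imputed-minimum copies as one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable
from .exceptions import UndefinedTestError

EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

def eligible_for_test(values, imputed_flags=None, min_unique: int = 20) -> bool:
    """At least ``min_unique`` unique values, imputed copies counted once.

    ``values`` is one group's observed vector (NaNs ignored);
    ``imputed_flags`` marks entries that were filled with the feature's
    imputed minimum — all such entries together contribute a single unique
    value.
    """
    v = np.asarray(values, dtype=float)
    if imputed_flags is None:
        imputed_flags = np.zeros(v.shape, dtype=bool)
    flags = np.asarray(imputed_flags, dtype=bool)
    present = ~np.isnan(v)
    observed = v[present & ~flags]
    n_unique = len(np.unique(observed))
    if (present & flags).any():
        n_unique += 1
    return n_unique >= min_unique


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by DP over the 2^n equiprobable sign assignments.

    ``ranks`` are midranks of |differences| (half-integers allowed); the DP
    convolves the distribution of W+ over doubled ranks so sums stay
    integral. Ties are handled for free: the DP never assumes distinctness.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(np.rint(2 * w_plus))
    cdf = dist[: w2 + 1].sum()
    sf = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _signed_rank_approx_p(w_plus: float, ranks: np.ndarray) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def paired_signed_rank(pre, post) -> tuple[float, float]:
    """Wilcoxon paired signed-rank test on ``post - pre``.

    Pairs with a missing value are dropped, then zero differences; the
    statistic is W+, the sum of midranks of positive differences. Exact
    enumeration for n <= 25 nonzero pairs, tie-corrected normal
    approximation beyond. Raises :class:`UndefinedTestError` when no nonzero
    difference remains.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise UndefinedTestError("pre and post must have equal length")
    d = post - pre
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise UndefinedTestError("no nonzero paired differences")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _signed_rank_exact_p(w_plus, ranks)
    else:
        p = _signed_rank_approx_p(w_plus, ranks)
    return w_plus, p


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples,
    tie-corrected normal approximation otherwise)."""
    a = np.asarray(a, dtype=float)
    a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float)
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise UndefinedTestError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def adjust_pvalues(
    raw_ps, method: str = "bonferroni", alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Adjust p-values and flag rejections (strict ``adjusted < alpha``).

    ``bonferroni``: adjusted = min(1, m*p). ``bh_fdr``: Benjamini-Hochberg
    step-up. Returns (adjusted, reject_flags).
    """
    raw = np.asarray(raw_ps, dtype=float)
    if raw.size == 0:
        return raw.copy(), np.zeros(0, dtype=bool)
    if np.any((raw < 0) | (raw > 1)):
        raise UndefinedTestError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        adjusted = np.minimum(1.0, raw * raw.size)
    elif method == "bh_fdr":
        adjusted = multipletests(raw, method="fdr_bh")[1]
    else:
        raise UndefinedTestError(f"unknown correction method {method!r}")
    return adjusted, adjusted < alpha


def change_summary(pre, post) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of the paired change ``post - pre``.

    SD is NaN when fewer than two complete pairs exist.
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise UndefinedTestError("no complete pairs")
    sd = float(d.std(ddof=1)) if d.size >= 2 else float("nan")
    return float(d.mean()), sd


def sd_ci_overlap(
    changes_a, changes_b, n_boot: int = 1000, seed: int = 0, level: float = 0.95
) -> bool:
    """Do the percentile-bootstrap CIs of the two groups' SDs intersect?"""
    a = np.asarray(changes_a, dtype=float)
    b = np.asarray(changes_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise UndefinedTestError("each group needs >= 3 values")
    rng = np.random.default_rng(seed)
    tail = 100.0 * (1.0 - level) / 2.0

    def ci(x):
        draws = x[rng.integers(0, x.size, (n_boot, x.size))].std(axis=1, ddof=1)
        return np.percentile(draws, [tail, 100.0 - tail])

    lo_a, hi_a = ci(a)
    lo_b, hi_b = ci(b)
    return bool(lo_a <= hi_b and lo_b <= hi_a)


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def run_differential(
    table: FeatureTable,
    arm: str,
    alpha: float = 0.05,
    method: str = "bonferroni",
    min_unique: int = 20,
) -> pd.DataFrame:
    """Paired pre-vs-post test for every eligible feature within one arm.

    Returns one row per feature: statistic, raw and adjusted p, mean/SD of
    change, direction and eligibility. Multiplicity is applied across all
    eligible features of the table (one analysis family).
    """
    meta = table.sample_meta
    in_arm = meta["arm"] == arm
    pre_ids = meta.index[in_arm & (meta["timepoint"] == "pre")]
    post_ids = meta.index[in_arm & (meta["timepoint"] == "post")]
    pre_by_p = pd.Series(pre_ids, index=meta.loc[pre_ids, "participant_id"])
    post_by_p = pd.Series(post_ids, index=meta.loc[post_ids, "participant_id"])
    common = pre_by_p.index.intersection(post_by_p.index)
    pre_rows = pre_by_p.loc[common].to_numpy()
    post_rows = post_by_p.loc[common].to_numpy()

    arm_rows = np.concatenate([pre_rows, post_rows])
    vals = table.values
    flags = table.imputed

    records = []
    for feat in vals.columns:
        group_vals = vals.loc[arm_rows, feat].to_numpy()
        group_flags = flags.loc[arm_rows, feat].to_numpy()
        eligible = eligible_for_test(group_vals, group_flags, min_unique)
        row = {
            "feature_id": feat,
            "arm": arm,
            "eligible": eligible,
            "statistic": np.nan,
            "raw_p": np.nan,
            "mean_change": np.nan,
            "sd_change": np.nan,
            "direction": pd.NA,
        }
        if eligible:
            pre_v = vals.loc[pre_rows, feat].to_numpy()
            post_v = vals.loc[post_rows, feat].to_numpy()
            try:
                stat, p = paired_signed_rank(pre_v, post_v)
                mean_c, sd_c = change_summary(pre_v, post_v)
            except UndefinedTestError:
                row["eligible"] = False
            else:
                row.update(
                    statistic=stat,
                    raw_p=p,
                    mean_change=mean_c,
                    sd_change=sd_c,
                    direction="up" if mean_c > 0 else "down",
                )
        records.append(row)

    results = pd.DataFrame(records).set_index("feature_id")
    results["adjusted_p"] = np.nan
    results["significant"] = False
    results["method"] = method
    tested = results.index[results["eligible"]]
    if len(tested):
        adjusted, reject = adjust_pvalues(
            results.loc[tested, "raw_p"].to_numpy(), method=method, alpha=alpha
        )
        results.loc[tested, "adjusted_p"] = adjusted
        results.loc[tested, "significant"] = reject
    return results


def baseline_screen(
    table: FeatureTable,
    arms: tuple[str, str] = ("PPT", "MED"),
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Between-arm Mann-Whitney screen on pre-intervention values.

    Used to confirm the two diet groups do not differ at baseline in any
    feature.
    """
    meta = table.sample_meta
    pre = meta["timepoint"] == "pre"
    rows_a = meta.index[pre & (meta["arm"] == arms[0])]
    rows_b = meta.index[pre & (meta["arm"] == arms[1])]
    records = []
    for feat in table.values.columns:
        a = table.values.loc[rows_a, feat].to_numpy()
        b = table.values.loc[rows_b, feat].to_numpy()
        try:
            u, p = mann_whitney(a, b)
        except UndefinedTestError:
            u, p = np.nan, np.nan
        records.append({"feature_id": feat, "statistic": u, "raw_p": p})
    results = pd.DataFrame(records).set_index("feature_id")
    ok = results["raw_p"].notna()
    results["adjusted_p"] = np.nan
    results["significant"] = False
    if ok.any():
        adjusted, reject = adjust_pvalues(
            results.loc[ok, "raw_p"].to_numpy(), method=method, alpha=alpha
        )
        results.loc[ok, "adjusted_p"] = adjusted
        results.loc[ok, "significant"] = reject
    return results
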