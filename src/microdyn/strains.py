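"""Strain-level dynamics from allele pileups.

The genetic dissimilarity between two samples of one species is the fraction
of comparable positions (total depth >= 3 reads in both samples) whose allele
sets share no member, computed only when at least 20,000 comparable positions
exist and clipped from below at 1/20,000 — the method's detection threshold.
An allele is "present" at a position if it carries at least
``max(1, presence_fraction * depth)`` reads (default 10%), a rule that
suppresses sequencing error at moderate depth without discarding true
within-sample heterogeneity.

A strain replacement is called for a (participant, species) pair when the
intra-person dissimilarity between the pre and post samples strictly exceeds
the lower 5% quantile (linear interpolation) of that species' inter-personal
dissimilarities — the distances between samples of different participants,
both timepoints included. By construction, a true replacement (a strain as
different from its predecessor as two strangers' strains) is missed about 5%
of the time.

Replacement calls aggregate to the percentage of species replaced per
participant and the percentage of carriers with a replacement per species,
which support the oral-vs-gut comparison (pooled and binned by the quantity
available for comparison) and the richness/prevalence correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DISSIM_COLUMNS, AllelePileup
from .exceptions import InvalidArgumentError, UndefinedInputError

MIN_POSITIONS = 20_000
MIN_DEPTH = 3
CLIP = 1.0 / 20_000
PRESENCE_FRACTION = 0.10

_BITS = np.array([1, 2, 4, 8], dtype=np.uint8)


# ---------------------------------------------------------------------------
# position-level primitives
# ---------------------------------------------------------------------------

def allele_set(counts_at_position, presence_fraction: float = PRESENCE_FRACTION):
    """Alleles with at least ``max(1, presence_fraction * depth)`` reads.

    Returns a frozenset over {"A", "C", "G", "T"}; empty at zero depth.
    """
    counts = np.asarray(counts_at_position, dtype=float)
    depth = counts.sum()
    if depth < 1:
        return frozenset()
    threshold = max(1.0, presence_fraction * depth)
    bases = np.array(["A", "C", "G", "T"])
    return frozenset(bases[counts >= threshold])


def _presence_mask(counts: np.ndarray, presence_fraction: float) -> np.ndarray:
    """Bit-encode per-position allele presence for one sample.

    ``counts`` is (n_positions, 4); returns uint8 with bit i set when allele
    i meets the presence rule.
    """
    depth = counts.sum(axis=1, dtype=np.int64)
    threshold = np.maximum(1.0, presence_fraction * depth)
    present = counts >= threshold[:, None]
    return (present.astype(np.uint8) * _BITS).sum(axis=1).astype(np.uint8)


def comparable_positions(
    pile_a: AllelePileup, pile_b: AllelePileup, min_depth: int = MIN_DEPTH
) -> np.ndarray:
    """Positions with total depth >= ``min_depth`` in BOTH samples."""
    if pile_a.species_id != pile_b.species_id:
        raise InvalidArgumentError("pileups must belong to the same species")
    common, ia, ib = np.intersect1d(
        pile_a.positions, pile_b.positions, return_indices=True
    )
    ok = (pile_a.depth[ia] >= min_depth) & (pile_b.depth[ib] >= min_depth)
    return common[ok]


def pairwise_dissimilarity(
    pile_a: AllelePileup,
    pile_b: AllelePileup,
    min_positions: int = MIN_POSITIONS,
    clip: float = CLIP,
    min_depth: int = MIN_DEPTH,
    presence_fraction: float = PRESENCE_FRACTION,
) -> dict:
    """No-common-allele dissimilarity between two pileups of one species.

    Returns a record dict with ``n_comparable`` and ``dissimilarity``
    (NaN when fewer than ``min_positions`` comparable positions exist;
    otherwise the fraction of comparable positions with disjoint allele
    sets, floored at ``clip``). Symmetric in its arguments.
    """
    common, ia, ib = np.intersect1d(
        pile_a.positions, pile_b.positions, return_indices=True
    )
    if pile_a.species_id != pile_b.species_id:
        raise InvalidArgumentError("pileups must belong to the same species")
    depth_ok = (pile_a.depth[ia] >= min_depth) & (pile_b.depth[ib] >= min_depth)
    n_comparable = int(depth_ok.sum())
    if n_comparable < min_positions:
        d = float("nan")
    else:
        mask_a = _presence_mask(pile_a.counts[ia[depth_ok]], presence_fraction)
        mask_b = _presence_mask(pile_b.counts[ib[depth_ok]], presence_fraction)
        disjoint = (mask_a & mask_b) == 0
        d = max(float(disjoint.sum()) / n_comparable, clip)
    return {
        "species_id": pile_a.species_id,
        "sample_a": pile_a.sample_id,
        "sample_b": pile_b.sample_id,
        "n_comparable": n_comparable,
        "dissimilarity": d,
    }


# ---------------------------------------------------------------------------
# species-level pair sets
# ---------------------------------------------------------------------------

def dissimilarity_sets(
    pileups: list[AllelePileup],
    pairing: pd.DataFrame,
    min_positions: int = MIN_POSITIONS,
    clip: float = CLIP,
    min_depth: int = MIN_DEPTH,
    presence_fraction: float = PRESENCE_FRACTION,
) -> pd.DataFrame:
    """All intra- and inter-personal dissimilarities, per species.

    ``pairing`` maps sample_id (index) to ``participant_id`` and
    ``timepoint``. Intra pairs are one participant's pre vs post samples;
    inter pairs are all sample pairs from different participants, both
    timepoints included. Returns a DataFrame with :data:`DISSIM_COLUMNS`
    (``dissimilarity`` is NaN for non-comparable pairs).

    A fast vectorized path is used when all of a species' pileups share one
    position grid (the synthetic-generator layout); otherwise each pair goes
    through :func:`pairwise_dissimilarity`.
    """
    records = []
    by_species: dict[str, list[AllelePileup]] = {}
    for p in pileups:
        by_species.setdefault(p.species_id, []).append(p)

    for species_id, piles in by_species.items():
        participants = [pairing.loc[p.sample_id, "participant_id"] for p in piles]
        shared_grid = all(
            np.array_equal(piles[0].positions, p.positions) for p in piles[1:]
        )
        n = len(piles)
        if shared_grid and n > 1:
            depth = np.stack([p.depth for p in piles])
            masks = np.stack(
                [_presence_mask(p.counts, presence_fraction) for p in piles]
            )
            deep = depth >= min_depth
            iu, ju = np.triu_indices(n, k=1)
            comp = deep[iu] & deep[ju]
            n_comp = comp.sum(axis=1)
            disjoint = ((masks[iu] & masks[ju]) == 0) & comp
            n_disjoint = disjoint.sum(axis=1)
            for k in range(iu.size):
                i, j = int(iu[k]), int(ju[k])
                nc = int(n_comp[k])
                d = (
                    max(float(n_disjoint[k]) / nc, clip)
                    if nc >= min_positions
                    else float("nan")
                )
                records.append(
                    _record(piles[i], piles[j], participants[i], participants[j], nc, d)
                )
        else:
            for i in range(n):
                for j in range(i + 1, n):
                    rec = pairwise_dissimilarity(
                        piles[i], piles[j], min_positions, clip,
                        min_depth, presence_fraction,
                    )
                    records.append(
                        _record(
                            piles[i], piles[j], participants[i], participants[j],
                            rec["n_comparable"], rec["dissimilarity"],
                        )
                    )
    return pd.DataFrame(records, columns=DISSIM_COLUMNS)


def _record(pile_a, pile_b, part_a, part_b, n_comparable, dissimilarity) -> dict:
    return {
        "species_id": pile_a.species_id,
        "sample_a": pile_a.sample_id,
        "sample_b": pile_b.sample_id,
        "participant_a": part_a,
        "participant_b": part_b,
        "n_comparable": n_comparable,
        "dissimilarity": dissimilarity,
        "pair_type": "intra_person" if part_a == part_b else "inter_person",
    }


# ---------------------------------------------------------------------------
# replacement calling
# ---------------------------------------------------------------------------

def replacement_threshold(
    inter_dissimilarities, q: float = 0.05, min_pairs: int = 1
) -> float | None:
    """Lower-``q`` quantile (linear interpolation) of the inter-personal
    dissimilarities; ``None`` when fewer than ``min_pairs`` values exist."""
    v = np.asarray(inter_dissimilarities, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < max(min_pairs, 1):
        return None
    return float(np.quantile(v, q))


def species_thresholds(
    records: pd.DataFrame, q: float = 0.05, min_inter_pairs: int = 10
) -> dict[str, float]:
    """Per-species replacement thresholds from a dissimilarity-record frame.

    Species with fewer than ``min_inter_pairs`` comparable inter-personal
    pairs are skipped — a 5% quantile of fewer values is not meaningful.
    """
    inter = records[
        (records["pair_type"] == "inter_person")
        & records["dissimilarity"].notna()
    ]
    out = {}
    for species_id, grp in inter.groupby("species_id"):
        t = replacement_threshold(
            grp["dissimilarity"].to_numpy(), q=q, min_pairs=min_inter_pairs
        )
        if t is not None:
            out[str(species_id)] = t
    return out


def call_replacements(
    records: pd.DataFrame, thresholds: dict[str, float]
) -> pd.DataFrame:
    """Call a replacement where intra dissimilarity strictly exceeds the
    species threshold.

    ``records`` is a dissimilarity frame; only comparable intra-person pairs
    of species with a threshold yield calls. Returns a frame with
    ``participant_id, species_id, intra_dissimilarity, threshold, replaced``.
    """
    intra = records[
        (records["pair_type"] == "intra_person")
        & records["dissimilarity"].notna()
    ]
    calls = pd.DataFrame(
        {
            "participant_id": intra["participant_a"].to_numpy(),
            "species_id": intra["species_id"].to_numpy(),
            "intra_dissimilarity": intra["dissimilarity"].to_numpy(dtype=float),
            "threshold": intra["species_id"].map(thresholds).to_numpy(dtype=float),
        }
    )
    calls = calls[calls["threshold"].notna()].reset_index(drop=True)
    calls["replaced"] = calls["intra_dissimilarity"] > calls["threshold"]
    return calls


def participant_replacement_rate(calls: pd.DataFrame) -> pd.Series:
    """Percent of compared species replaced, per participant."""
    if calls.empty:
        raise UndefinedInputError("no replacement calls")
    grp = calls.groupby("participant_id")["replaced"]
    return 100.0 * grp.sum() / grp.count()


def species_replacement_rate(calls: pd.DataFrame) -> pd.Series:
    """Percent of carriers with a replacement, per species."""
    if calls.empty:
        raise UndefinedInputError("no replacement calls")
    grp = calls.groupby("species_id")["replaced"]
    return 100.0 * grp.sum() / grp.count()


# ---------------------------------------------------------------------------
# environment comparison and correlations
# ---------------------------------------------------------------------------

def compare_environments(
    oral_rates: pd.DataFrame,
    gut_rates: pd.DataFrame,
    bin_width: int = 10,
) -> dict:
    """Oral vs gut replacement rates, pooled and binned by comparison count.

    Each input frame has columns ``rate`` (percent replaced) and
    ``n_compared`` (species or participants available for comparison). The
    pooled comparison is a two-sided Mann-Whitney U test; the binned version
    groups units into ``bin_width``-wide count bins and tests within each
    bin that contains both environments (others are skipped with a note).
    """
    pooled_u, pooled_p = stats.mannwhitneyu(
        oral_rates["rate"], gut_rates["rate"], alternative="two-sided"
    )
    bins = {}
    skipped = []
    oral_bin = (oral_rates["n_compared"] // bin_width).astype(int)
    gut_bin = (gut_rates["n_compared"] // bin_width).astype(int)
    for b in sorted(set(oral_bin) | set(gut_bin)):
        a = oral_rates.loc[oral_bin == b, "rate"]
        g = gut_rates.loc[gut_bin == b, "rate"]
        if len(a) == 0 or len(g) == 0:
            skipped.append(int(b))
            continue
        u, p = stats.mannwhitneyu(a, g, alternative="two-sided")
        bins[int(b)] = {
            "U": float(u), "p": float(p),
            "n_oral": int(len(a)), "n_gut": int(len(g)),
        }
    return {
        "pooled": {"U": float(pooled_u), "p": float(pooled_p)},
        "bins": bins,
        "skipped_bins": skipped,
    }


def dynamics_correlation(rates, covariate) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between replacement rates and a
    paired covariate (participant-level richness or species-level
    prevalence). Pairs with a missing value are dropped."""
    df = pd.DataFrame({"rate": rates, "cov": covariate}).dropna()
    if df["rate"].nunique() < 2 or df["cov"].nunique() < 2:
        raise UndefinedInputError("correlation undefined for constant input")
    r, p = stats.pearsonr(df["rate"], df["cov"])
    return float(r), float(p)


def intra_dissimilarity_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Participants x species matrix of comparable intra-person
    dissimilarities (NaN where not comparable); mediator input for the
    strain mediation screen."""
    intra = records[
        (records["pair_type"] == "intra_person")
        & records["dissimilarity"].notna()
    ]
    return intra.pivot_table(
        index="participant_a", columns="species_id", values="dissimilarity"
    ).rename_axis(index="participant_id")
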