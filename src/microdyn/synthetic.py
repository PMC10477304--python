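"""Synthetic cohorts, paired multi-omic tables, diet logs and allele pileups.

This module emulates the data shapes of a paired pre/post dietary-intervention
trial with two arms (a personalized postprandial-glucose-targeting diet, PPT,
and a Mediterranean diet, MED) so that every downstream stage — preprocessing,
paired differential testing, mediation screening and strain-replacement
calling — can be exercised and verified by parameter recovery against a known
:class:`GroundTruth`.

Modelling choices (see docs/methods.md for rationale):

* Species, pathway and metabolite baselines are log-normal (the preprocessing
  chain begins with a log10 transform); cytokine baselines are normal on an
  NPX-like arbitrary scale.
* Planted pre->post shifts are expressed in within-feature total-SD units and
  added on the latent (log) scale, so they survive standardization unchanged.
* Strain haplotypes are drawn from a shared population pool per species, so
  the inter-personal dissimilarity distribution — the replacement caller's
  null — is well defined, and a planted replacement is an exchangeable draw
  from that same pool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AllelePileup, FeatureTable
from .exceptions import InvalidArgumentError

ARMS = ("PPT", "MED")
TIMEPOINTS = ("pre", "post")

#: (assay name, count attribute on PanelSpec, distribution family)
_PANEL_BLOCKS = (
    ("gut_species", "n_gut_species", "lognormal"),
    ("oral_species", "n_oral_species", "lognormal"),
    ("gut_pathways", "n_gut_pathways", "lognormal"),
    ("oral_pathways", "n_oral_pathways", "lognormal"),
    ("metabolites", "n_metabolites", "lognormal"),
    ("cytokines", "n_cytokines", "normal"),
)

# Variance split of the latent per-feature signal: participant-level random
# effect vs. per-timepoint noise. Total latent SD is 1 by construction, so
# planted shifts in "SD units" add directly on the latent scale.
_SIGMA_BETWEEN = 0.8
_SIGMA_WITHIN = 0.6


@dataclass
class PanelSpec:
    """Feature counts and nuisance structure of the measured panels.

    The default counts reproduce the full measured panel: 605 gut and 336
    oral microbial species, 380 gut and 311 oral microbial pathways, 1095
    serum metabolites and 76 cytokines — 2,803 features in total.
    """

    n_gut_species: int = 605
    n_oral_species: int = 336
    n_gut_pathways: int = 380
    n_oral_pathways: int = 311
    n_metabolites: int = 1095
    n_cytokines: int = 76
    missingness_rate: float = 0.05
    batch_count: int = 2
    batch_shift: float = 0.0  # in feature-SD units along a random direction

    def __post_init__(self) -> None:
        counts = [getattr(self, f.name) for f in self.__dataclass_fields__.values()
                  if f.name.startswith("n_")]
        if any(c < 0 for c in counts):
            raise InvalidArgumentError("panel counts must be >= 0")
        if not 0 <= self.missingness_rate < 1:
            raise InvalidArgumentError("missingness_rate must be in [0, 1)")
        if self.batch_count < 1:
            raise InvalidArgumentError("batch_count must be >= 1")

    @property
    def n_features(self) -> int:
        return sum(getattr(self, attr) for _, attr, _ in _PANEL_BLOCKS)


@dataclass
class EffectSpec:
    """Planted pre->post intervention effects.

    ``fraction_affected`` defaults to 0.06, matching the order of magnitude
    of significantly changed features reported for this kind of trial
    (166 of 2,803); ``shift_mean`` is a moderate 1-SD effect.
    """

    fraction_affected: float = 0.06
    shift_mean: float = 1.0
    shift_sd: float = 0.25
    arm_specific: bool = True
    arm: str = "PPT"

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_affected <= 1:
            raise InvalidArgumentError("fraction_affected must be in [0, 1]")


@dataclass
class PileupSpec:
    """Shape and noise model of synthetic allele pileups."""

    n_species: int = 12
    n_positions: int = 30_000
    depth_mean: float = 20.0
    replacement_prob: float = 0.3
    inter_divergence: float = 0.02
    error_rate: float = 0.01
    n_pool_strains: int = 20

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise InvalidArgumentError("n_positions must be >= 1")
        for name in ("replacement_prob", "inter_divergence", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidArgumentError(f"{name} must be in [0, 1]")
        if self.n_pool_strains < 2:
            raise InvalidArgumentError("n_pool_strains must be >= 2")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset, for recovery tests.

    ``affected_features`` maps feature id -> planted shift (SD units); its
    key set is the set of truly changed features. ``replaced`` holds
    (participant_id, species_id) pairs with a planted strain replacement.
    ``med_paths`` lists planted (a, b, c_prime) mediation coefficients.
    ``violating_days`` holds (participant_id, date, reason) for planted
    diet-log exclusion-rule violations.
    """

    affected_features: dict[str, float] = field(default_factory=dict)
    replaced: set = field(default_factory=set)
    med_paths: list = field(default_factory=list)
    violating_days: set = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "affected_features": self.affected_features,
            "replaced": sorted(list(t) for t in self.replaced),
            "med_paths": [list(t) for t in self.med_paths],
            "violating_days": sorted(list(t) for t in self.violating_days),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            affected_features=payload["affected_features"],
            replaced={tuple(t) for t in payload["replaced"]},
            med_paths=[tuple(t) for t in payload["med_paths"]],
            violating_days={tuple(t) for t in payload["violating_days"]},
        )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def generate_cohort(n_per_arm: int, seed: int = 0) -> pd.DataFrame:
    """Generate a balanced two-arm cohort.

    Returns a DataFrame indexed by ``participant_id`` with columns ``arm``
    (PPT/MED, exactly ``n_per_arm`` each), ``age`` (years), ``sex`` (M/F) and
    ``bmi`` (kg/m^2). Baseline distributions match a middle-aged pre-diabetic
    cohort (age ~ N(50.6, 7.9) clipped to 18-65, BMI ~ N(30.8, 5.6), ~44%
    male). Deterministic given ``seed``.
    """
    if n_per_arm < 1:
        raise InvalidArgumentError("n_per_arm must be >= 1")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    ids = [f"P{i:04d}" for i in range(1, n + 1)]
    arm = np.repeat(ARMS, n_per_arm)
    age = np.clip(rng.normal(50.6, 7.9, n), 18, 65)
    bmi = np.clip(rng.normal(30.8, 5.6, n), 17, 55)
    sex = np.where(rng.random(n) < 0.44, "M", "F")
    cohort = pd.DataFrame(
        {"arm": arm, "age": age, "sex": sex, "bmi": bmi},
        index=pd.Index(ids, name="participant_id"),
    )
    return cohort


def sample_pairing(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sample metadata (participant, timepoint, arm) for the paired design.

    Sample ids are ``<participant_id>-pre`` / ``<participant_id>-post``.
    """
    rows = []
    for pid, row in cohort.iterrows():
        for tp in TIMEPOINTS:
            rows.append((f"{pid}-{tp}", pid, tp, row["arm"]))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "participant_id", "timepoint", "arm"]
    ).set_index("sample_id")
    return meta


# ---------------------------------------------------------------------------
# paired feature tables
# ---------------------------------------------------------------------------

def generate_paired_features(
    cohort: pd.DataFrame,
    panel: PanelSpec | None = None,
    effect: EffectSpec | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, GroundTruth]:
    """Generate one pre and one post sample per participant for every panel.

    A fraction ``effect.fraction_affected`` of features receives a planted
    post-minus-pre shift drawn from Normal(shift_mean, shift_sd), expressed
    in within-feature total-SD units (applied on the latent log scale for
    log-normal assays). If ``panel.batch_shift`` > 0, samples are assigned to
    ``panel.batch_count`` batches and offset along a fixed random direction.
    Missing entries are planted completely at random at
    ``panel.missingness_rate``.
    """
    panel = panel or PanelSpec()
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)

    meta = sample_pairing(cohort)
    participants = cohort.index.to_numpy()
    n_p = len(participants)
    n_feat = panel.n_features

    feature_ids, assay_labels, families = [], [], []
    for assay, attr, family in _PANEL_BLOCKS:
        count = getattr(panel, attr)
        feature_ids.extend(f"{assay}_{i:04d}" for i in range(1, count + 1))
        assay_labels.extend([assay] * count)
        families.extend([family] * count)
    families = np.array(families)

    # latent per-feature locations
    mu = np.empty(n_feat)
    lognorm = families == "lognormal"
    mu[lognorm] = rng.uniform(-4.0, -1.0, lognorm.sum())  # log10 abundances
    mu[~lognorm] = rng.uniform(5.0, 10.0, (~lognorm).sum())  # NPX-like

    z = rng.normal(0.0, _SIGMA_BETWEEN, (n_p, n_feat))  # participant effect
    e_pre = rng.normal(0.0, _SIGMA_WITHIN, (n_p, n_feat))
    e_post = rng.normal(0.0, _SIGMA_WITHIN, (n_p, n_feat))

    latent_pre = mu + z + e_pre
    latent_post = mu + z + e_post

    # planted intervention effects
    truth = GroundTruth()
    n_aff = int(round(effect.fraction_affected * n_feat))
    if n_aff:
        aff_idx = rng.choice(n_feat, size=n_aff, replace=False)
        shifts = rng.normal(effect.shift_mean, effect.shift_sd, n_aff)
        if effect.arm_specific:
            affected_p = (cohort["arm"] == effect.arm).to_numpy()
        else:
            affected_p = np.ones(n_p, dtype=bool)
        latent_post[np.ix_(affected_p, aff_idx)] += shifts
        truth.affected_features = {
            feature_ids[j]: float(s) for j, s in zip(aff_idx, shifts)
        }

    # batch structure along a fixed random direction (RMS-1 so batch_shift
    # is the typical per-feature offset in SD units)
    n_samples = 2 * n_p
    batches = rng.integers(0, panel.batch_count, n_samples)
    if panel.batch_shift > 0 and panel.batch_count > 1:
        v = rng.normal(0.0, 1.0, n_feat)
        v /= np.sqrt(np.mean(v**2))
        centered = batches - batches.mean()
        offset = panel.batch_shift * np.outer(centered, v)
    else:
        offset = np.zeros((n_samples, n_feat))

    # interleave pre/post rows in the meta order (pid-pre, pid-post, ...)
    latent = np.empty((n_samples, n_feat))
    latent[0::2] = latent_pre
    latent[1::2] = latent_post
    latent += offset

    raw = np.where(lognorm, 10.0 ** latent, latent)
    raw[:, ~lognorm] = np.maximum(raw[:, ~lognorm], 1e-6)

    if panel.missingness_rate > 0:
        raw[rng.random(raw.shape) < panel.missingness_rate] = np.nan

    values = pd.DataFrame(raw, index=meta.index, columns=feature_ids)
    meta = meta.assign(assay="multi", batch=batches)
    feature_meta = pd.DataFrame(
        {"assay": assay_labels, "family": families},
        index=pd.Index(feature_ids, name="feature_id"),
    )
    table = FeatureTable(values, meta, feature_meta)
    return table, truth


# ---------------------------------------------------------------------------
# diet logs
# ---------------------------------------------------------------------------

_VIOLATION_RULES = ("low_calories", "high_calories", "unmatched")


def generate_diet_logs(
    cohort: pd.DataFrame,
    n_days: int = 28,
    violation_rates: dict | None = None,
    seed: int = 0,
    profiling_days: int = 14,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate daily diet logs with planted exclusion-rule violations.

    Each participant gets ``n_days`` records; the first ``profiling_days``
    belong to the ``profiling`` period, the rest to ``intervention``. A day
    violates at most one planted rule: ``low_calories`` (< 60% of the
    personal caloric target), ``high_calories`` (> 240% of target) or
    ``unmatched`` (> 20% of reported calories not matched to the food
    database). Clean days are confined to the safe band (65-235% of target,
    unmatched <= 18%) so the planted truth is exactly the exclusion set.
    """
    if n_days < 1:
        raise InvalidArgumentError("n_days must be >= 1")
    rates = dict.fromkeys(_VIOLATION_RULES, 0.0)
    if violation_rates:
        unknown = set(violation_rates) - set(_VIOLATION_RULES)
        if unknown:
            raise InvalidArgumentError(f"unknown violation rules: {sorted(unknown)}")
        rates.update(violation_rates)
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    rows = []
    for pid in cohort.index:
        target = float(np.round(rng.normal(2000, 250), 0))
        for day in range(n_days):
            date = f"d{day:03d}"
            period = "profiling" if day < profiling_days else "intervention"
            # at most one planted violation per day
            reason = None
            for rule in _VIOLATION_RULES:
                if rng.random() < rates[rule]:
                    reason = rule
                    break
            unmatched = rng.uniform(0.0, 0.18)
            if reason == "low_calories":
                calories = target * rng.uniform(0.20, 0.55)
            elif reason == "high_calories":
                calories = target * rng.uniform(2.50, 3.20)
            else:
                calories = target * np.clip(rng.normal(1.0, 0.12), 0.65, 2.35)
                if reason == "unmatched":
                    unmatched = rng.uniform(0.25, 0.60)
            if reason is not None:
                truth.violating_days.add((pid, date, reason))
            carb_frac = np.clip(rng.normal(0.48, 0.06), 0.2, 0.7)
            fat_frac = np.clip(rng.normal(0.33, 0.05), 0.1, 0.6)
            prot_frac = max(1.0 - carb_frac - fat_frac, 0.05)
            rows.append(
                {
                    "participant_id": pid,
                    "date": date,
                    "period": period,
                    "calories": calories,
                    "caloric_target": target,
                    "unmatched_fraction": unmatched,
                    "carbohydrates_g": calories * carb_frac / 4.0,
                    "protein_g": calories * prot_frac / 4.0,
                    "lipids_g": calories * fat_frac / 9.0,
                    "fiber_g": rng.uniform(10, 40),
                }
            )
    logs = pd.DataFrame(rows)
    return logs, truth


# ---------------------------------------------------------------------------
# allele pileups
# ---------------------------------------------------------------------------

def _mutation_prob(inter_divergence: float) -> float:
    """Per-position mutation probability m such that two independent pool
    strains disagree at a fraction ``inter_divergence`` of positions.

    P(disagree) = 2m(1-m) + (2/3)m^2 = 2m - (4/3)m^2; solved for m.
    """
    d = inter_divergence
    if d == 0:
        return 0.0
    return (2.0 - np.sqrt(4.0 - (16.0 / 3.0) * d)) / (8.0 / 3.0)


def generate_pileups(
    cohort: pd.DataFrame,
    spec: PileupSpec | None = None,
    seed: int = 0,
) -> tuple[list[AllelePileup], GroundTruth]:
    """Generate per-(species, sample) allele pileups with planted replacements.

    For each species a pool of ``spec.n_pool_strains`` haplotypes is drawn
    around a random reference; each participant carries one pool strain at
    both timepoints unless a replacement is planted (probability
    ``spec.replacement_prob``), in which case the post sample carries a
    different pool strain. Read depth per position is Poisson(depth_mean);
    each read reports the true allele except with probability ``error_rate``,
    in which case all of a position's error reads go to one random other
    allele.
    """
    spec = spec or PileupSpec()
    rng = np.random.default_rng(seed)
    participants = cohort.index.to_numpy()
    n_p = len(participants)
    P = spec.n_positions
    m = _mutation_prob(spec.inter_divergence)

    pileups: list[AllelePileup] = []
    truth = GroundTruth()
    positions = np.arange(P, dtype=np.int64)

    for s in range(spec.n_species):
        species_id = f"SGB_{s:04d}"
        ref = rng.integers(0, 4, P)
        pool = np.tile(ref, (spec.n_pool_strains, 1))
        mut = rng.random((spec.n_pool_strains, P)) < m
        shift = rng.integers(1, 4, (spec.n_pool_strains, P))
        pool[mut] = (pool[mut] + shift[mut]) % 4

        pre_idx = rng.integers(0, spec.n_pool_strains, n_p)
        post_idx = pre_idx.copy()
        replace = rng.random(n_p) < spec.replacement_prob
        for i in np.where(replace)[0]:
            choices = np.delete(np.arange(spec.n_pool_strains), pre_idx[i])
            post_idx[i] = rng.choice(choices)
            truth.replaced.add((participants[i], species_id))

        for pid, strain_pre, strain_post in zip(participants, pre_idx, post_idx):
            for tp, strain_idx in (("pre", strain_pre), ("post", strain_post)):
                hap = pool[strain_idx]
                depth = rng.poisson(spec.depth_mean, P)
                errors = rng.binomial(depth, spec.error_rate)
                err_allele = (hap + rng.integers(1, 4, P)) % 4
                counts = np.zeros((P, 4), dtype=np.int16)
                np.put_along_axis(
                    counts, hap[:, None], (depth - errors)[:, None].astype(np.int16), 1
                )
                # add error reads (may coincide with nothing else; hap slot untouched)
                idx = (np.arange(P), err_allele)
                counts[idx] += errors.astype(np.int16)
                pileups.append(
                    AllelePileup(species_id, f"{pid}-{tp}", positions, counts)
                )
    return pileups, truth


# ---------------------------------------------------------------------------
# mediation triplets
# ---------------------------------------------------------------------------

def generate_mediation_data(
    cohort: pd.DataFrame,
    a: float,
    b: float,
    c_prime: float = 0.0,
    sigma: float = 0.5,
    seed: int = 0,
    gamma: np.ndarray | None = None,
    delta: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate one mediation triplet X -> M -> Y over the cohort.

    ``M = a*X + gamma'cov + eps`` and ``Y = b*M + c_prime*X + delta'cov + eps'``
    with iid Normal(0, sigma) noise. Covariates are (age, sex, BMI) taken
    from the cohort, with sex encoded as a 0/1 indicator; their effects
    ``gamma``/``delta`` default to zero so path recovery is isolated.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    cov = pd.DataFrame(
        {
            "age": cohort["age"].to_numpy(),
            "sex": (cohort["sex"] == "M").astype(float).to_numpy(),
            "bmi": cohort["bmi"].to_numpy(),
        },
        index=cohort.index,
    )
    gamma = np.zeros(3) if gamma is None else np.asarray(gamma, float)
    delta = np.zeros(3) if delta is None else np.asarray(delta, float)
    X = rng.normal(0.0, 1.0, n)
    M = a * X + cov.to_numpy() @ gamma + rng.normal(0.0, sigma, n)
    Y = b * M + c_prime * X + cov.to_numpy() @ delta + rng.normal(0.0, sigma, n)
    return X, M, Y, cov
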