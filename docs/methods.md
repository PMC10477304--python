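# Methods

This note records the models, conventions and design choices behind
`microdyn`, the assumptions of its synthetic-data generator, and the
numerical details a user would need to reproduce or audit its behaviour.

## Study design emulated

The package targets a two-arm, paired pre/post dietary-intervention design:
each participant contributes one pre- and one post-intervention sample per
assay (gut/oral microbial species and pathways, serum metabolites,
cytokines), daily diet logs with a personal caloric target, and per-species
allele pileups at two timepoints. Arms are a personalized
postprandial-glucose-targeting diet (PPT) and a Mediterranean diet (MED).
Baseline covariates are age (years), sex and BMI (kg/m²).

## Preprocessing chain

Six steps, applied per assay in this exact order:

1. **log10.** Positive values only; zeros are converted to missing. A
   relative-abundance zero denotes non-detection, and the paired-minimum
   imputation step exists precisely to fill such holes, so treating zeros as
   missing (rather than adding a pseudocount) keeps one consistent
   missing-data mechanism.
2. **Robust standardization.** `(x − m)/s` where `m` and `s` are the median
   and sample SD (ddof = 1) of the values between the 5th and 95th
   percentiles (linear-interpolation percentiles, bounds inclusive). The
   "central 90%" convention is fixed so tests can be exact. Features with
   fewer than 3 observed values or zero central spread are flagged
   degenerate and left unstandardized.
3. **Clipping** to [−5, +5]. After step 2 the scale is robust-SD units, so
   "five standard deviations from the mean" becomes a fixed, idempotent
   interval.
4. **Prevalence filter.** Features observed in fewer than 20 samples are
   removed (a feature in exactly 20 samples is retained).
5. **Paired-minimum imputation.** A missing (participant, timepoint) cell
   receives the feature's minimum observed value — computed over both
   timepoints pooled, at the time of imputation — iff the participant's
   complementary sample has a value. Imputed cells are flagged; the flags
   feed the uniqueness rule of the differential tests.
6. **PC batch correction.** One PCA of the mean-centered matrix (missing
   cells filled with feature means for the decomposition only). Each of the
   first five components with explained variance ≥ 5% whose scores differ by
   batch (two-sided Mann–Whitney p < 0.05; smallest pairwise p when more
   than two batches, uncorrected) is reconstructed and subtracted in a
   single pass — no re-decomposition after each removal, matching the fixed
   "PCs reduced" accounting this rule is meant to reproduce.

Dietary features bypass steps 1, 2, 5, 6 and get clipping and the
prevalence filter only; since diet data is not standardized, the clip
bounds are the feature's own mean ± 5 SD.

Two consequences worth knowing. First, because batch correction runs after
clipping, a removed component's subtraction can push a handful of values
slightly past ±5; the clipping bound is a property of step 3, not of the
chain output. Second, at desk scale (tens of features, tens of samples) the
top noise eigenvalue of an iid matrix exceeds the 5% variance gate, so
component removal is then governed solely by the batch-association test and
fires spuriously at its nominal ~5% rate per candidate component; at
realistic panel sizes (hundreds of features, hundreds of samples) the
variance gate binds and the chain is idempotent on batch-free data, which
is what the idempotency test checks.

**Diet-day exclusion.** A day is excluded iff calories < 60% or > 240% of
the personal daily caloric target, or the unmatched-calorie fraction
exceeds 20%; missing targets exclude the day with reason `no-target`.
Retained days are averaged per participant and period
(profiling/intervention).

## Differential testing

- **Eligibility:** a feature is tested in a group only if it shows ≥ 20
  unique values there, counting all imputed-minimum copies as a single
  value.
- **Wilcoxon paired signed-rank:** zero differences are dropped; ties in
  |difference| get midranks; the statistic is W⁺. For n ≤ 25 nonzero pairs
  the two-sided p comes from exact enumeration of all 2ⁿ sign assignments,
  implemented as a dynamic-programming convolution over doubled midranks
  (which handles ties exactly); beyond 25, a tie-corrected normal
  approximation without continuity correction. The exact path is
  cross-checked against brute-force enumeration and, in the tie-free case,
  against scipy.
- **Mann–Whitney U** (between-arm baseline screen and the oral-vs-gut
  comparisons) delegates to scipy's implementation (exact for small
  tie-free samples, tie-corrected asymptotic otherwise).
- **Multiplicity:** Bonferroni (`min(1, m·p)`) by default; BH-FDR as the
  lenient alternative for low-powered panels. Rejection is strict
  (`adjusted < α`) for both — the literal reading fixed for testability;
  it preserves BH ⊇ Bonferroni. The family is all eligible features of one
  analysis (configurable); the all-null safety check treats an entire run's
  tests as one family.
- **Change summaries** are mean ± sample SD (ddof = 1) of post − pre; the
  equality-of-spread check bootstraps each group's SD (1,000 percentile
  resamples, seeded) and reports whether the 95% CIs intersect.

## Mediation

OLS of `M ~ 1 + X + cov` gives path a; OLS of `Y ~ 1 + X + M + cov` gives
b (coefficient of M) and c′ (coefficient of X). Case-resampling bootstrap
(default 500 resamples, seed 42; both regressions refitted per resample via
batched normal equations) yields draws of a, b and a·b; each two-sided p is
`2·min(frac ≤ 0, frac ≥ 0)` floored at 1/n_boot. Significance is the
two-path rule: p_a < α AND p_b < α. The indirect effect is reported as a·b
exactly. Sex enters as a 0/1 indicator; covariate effects default to zero
in the generator so path recovery is isolated. No multiplicity correction
is applied across trajectories by default (screens report p < 0.05), and
the candidate sets are restricted upstream to significantly changed
features. For strain mediators the diets are pooled, mediators are the ten
most-replaced species among those carried by strictly more than 50
participants, and |X|, |M|, |Y| are used because dissimilarity carries no
sign. Under an a = b = 0 null the two-path rule fires at ≈ α² ≪ α, which
the null-calibration test verifies empirically.

The bootstrap construction (rather than parametric regression p-values) is
the package's reading of "two-sided bootstrap" significance; the point
estimates are cross-checked against pingouin in the test suite.

## Strain dynamics

- **Allele presence:** an allele exists at a position if it has
  ≥ max(1, 0.10·depth) reads. The 10% fraction (a config knob) suppresses
  sequencing error at depth ≥ 3 without discarding genuine within-sample
  heterogeneity.
- **Comparability:** positions with total depth ≥ 3 in *both* samples (the
  "at least three reads" requirement is read as per-sample, not summed);
  a pair is scored only with ≥ 20,000 comparable positions.
- **Dissimilarity:** fraction of comparable positions whose allele sets are
  disjoint, floored at 1/20,000 (the detection threshold). Symmetric by
  construction; range [1/20,000, 1].
- **Null and calling:** per species, the inter-personal distribution pools
  all sample pairs from different participants, both timepoints included.
  The replacement threshold is the lower-5% quantile (linear
  interpolation); species with fewer than 10 comparable inter pairs are
  skipped, since a 5% quantile of fewer values is meaningless. "Exceeds" is
  strict. By construction a true replacement — an intra pair distributed
  like an inter pair — is missed ~5% of the time; the acceptance script
  measures exactly this.
- **Aggregation:** percent of compared species replaced per participant;
  percent of carriers with a replacement per species. Environment
  comparisons (oral vs gut) use pooled and count-binned Mann–Whitney tests;
  stability correlates are Pearson r of rate vs environment richness
  (participant level) and rate vs species prevalence (species level).

## Change-prediction evaluation

The external predictor is deliberately *not* re-implemented: the interface
accepts any callable or serialized linear map, and tests use a synthetic
linear predictor. Predicted change is predict(post) − predict(pre).
Metabolites split at training R² = 0.05; the headline score is the Pearson
r between per-metabolite mean observed and mean predicted change (matching
the axes the measurement is defined by), with a participant-level pooled
mode as an option. Variance explained is identically 100·r². Strata with
fewer than 3 metabolites are skipped.

## Synthetic-data generator

What it emulates, and how:

- **Cohort:** balanced arms; age ~ N(50.6, 7.9) clipped to 18–65, BMI ~
  N(30.8, 5.6), ~44% male — a middle-aged pre-diabetic cohort.
- **Feature panels:** defaults 605 + 336 + 380 + 311 + 1095 + 76 = 2,803
  features. Species/pathway/metabolite baselines are log-normal (log10
  locations uniform in [−4, −1]); cytokines are normal on an NPX-like
  scale. The processing chain starts with log10, which motivates the
  log-normal families; the true distributional families of the assays are
  unknown, so this is a modelling choice, not a claim.
- **Latent variance split:** participant random effect SD 0.8 and
  timepoint noise SD 0.6 (total latent SD 1), so planted shifts "in SD
  units" add directly and paired differences have SD ≈ 0.85.
- **Effects:** a fraction of features (default 6%, the order of magnitude
  of significant findings in trials of this kind) gets a shift ~
  N(1.0, 0.25) SD in the PPT arm by default.
- **Batch structure:** optional offset of size `batch_shift` SD along one
  fixed random direction — exactly the structure the PC-removal step
  targets.
- **Diet logs:** clean days live inside the retention band (65–235% of
  target, ≤ 18% unmatched); planted violations fall clearly outside, so the
  exclusion truth is exact.
- **Pileups:** each species has a pool of 20 haplotypes mutated from a
  random reference at per-position probability m chosen so two pool strains
  disagree at the requested inter-personal divergence
  (P(disagree) = 2m − (4/3)m²; default divergence 2%, within the up-to-5%
  genetic difference that separates strains of one species). Participants
  draw one pool strain; replacements (default probability 0.3) draw a
  different one, making planted replacements exchangeable with inter pairs
  — the property the quantile null requires. Depth is Poisson (default
  mean 20 over 30,000 positions); read errors (rate 0.01) send all of a
  position's error reads to one random alternative allele, a simplification
  that is immaterial at the presence rule's operating point.
- **Mediation triplets:** X ~ N(0,1), M = aX + γᵀcov + ε,
  Y = bM + c′X + δᵀcov + ε′, with γ = δ = 0 by default.

What it does **not** emulate: compositionality (features are independent,
not closed to a sum), phylogenetic or functional correlation between
features, longitudinal drift within a timepoint, depth-dependent
missingness, real strain phylogenies (the pool is a star, not a tree), and
assay-specific error structure. Passing recovery tests therefore
demonstrates the correctness and calibration of the algorithms under their
own stated assumptions — not robustness to the full messiness of real
trial data.

## Problem sizes and determinism

Test-suite and pipeline runs use deliberately scaled-down studies chosen as
the smallest sizes at which each property is identifiable: recovery tests
run 16–100 participants; strain recovery uses 12 species × 16 participants
at the full 30K-position depth-20 conditions; the differential-recovery
check runs the full 2,803-feature panel at 50 participants/arm; the
replacement-caller calibration uses 500 species × (1,000 inter + 200 intra)
draws. The default `RunConfig` is similarly desk-scale (25/arm, ~280
features, 4 species at 22K positions) and completes in seconds; the
generator specs themselves default to full panel sizes. Every stage's RNG
derives from a single config seed; all stochastic procedures (bootstraps,
generators) take explicit seeds and reproduce bit-identically.

## Known limitations

- The batch-association rule is uncorrected across components and batch
  pairs, so spurious removals occur at the nominal rate (see above).
- The exact signed-rank path is O(n³) in the DP but capped at n = 25.
- The mediation bootstrap resamples cases; it does not implement
  bias-corrected (BCa) intervals, sensitivity analysis or multiple
  mediators per model.
- Replacement calling assumes exactly two timepoints; multi-timepoint
  strain tracking is out of scope.
- URA abundance treats "densest areas" as individual positions (top ⌈n/2⌉
  by coverage), not fixed-width windows, and normalizes scores to relative
  abundance; platform-specific subsampling thresholds are recorded in
  config but not enforced on synthetic input.
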