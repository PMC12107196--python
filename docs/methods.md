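# Methods

This note documents the models and procedures `edrisk` implements, the
calibration of the synthetic registry, the numerical choices, and what the
passing tests do and do not establish about real data.

## The stratification procedure

The unit of analysis is one ED presentation with a single primary ICD-10
diagnosis. The pipeline estimates each code's admission risk as the plain
binomial fraction `r_c = a_c / n_c`, excludes codes with fewer than
`min_count = 15` presentations (rare codes produce risk estimates whose
binomial noise behaves as outliers in the clustering; 10 is the
conventional sensitivity value, and both thresholds keep the excluded
records a sub-percent fraction of a registry at scale), and clusters the
retained codes in one dimension.

**Clustering unit.** One point per code, unweighted by code frequency: the
stratification is of *diagnoses*, not presentations, and per-cluster code
counts should partition the code universe. `kmeans_1d(..., weights=...)`
offers frequency weighting, off by default. An alternative block-level mode
clusters pooled block risks instead (`level="block"`), the coarser
sensitivity operationalisation.

**Distance and labels.** Squared Euclidean distance on the raw risk
fraction — risks are already commensurate on [0, 1] and no transform is
applied. Cluster labels are always reported in ascending-centroid order, so
label 1 is the lowest-risk stratum everywhere (tables, block summaries, the
ordinal outcome).

## 1-D k-means: solver and oracle

`kmeans_1d` is Lloyd's algorithm with `n_init = 50` random restarts.
Numerical choices, in one place:

- **Seeding.** Initial centroids are drawn without replacement from the
  distinct data values, D²-weighted (k-means++ style): uniform first draw,
  then each further centroid with probability proportional to its squared
  distance from the nearest chosen one. Uniform seeding leaves Lloyd in
  shallow local optima with non-negligible probability on small
  near-uniform instances; D² weighting concentrates restarts on separating
  starts.
- **Assignment ties.** A value equidistant to two centroids joins the
  lower-risk one (deterministic, since centroids are kept sorted).
- **Empty clusters.** An emptied cluster is reseeded with the point
  farthest from its current centroid, keeping k fixed.
- **Convergence.** Stop when the largest centroid movement is below
  `tol = 1e-10`, or after `max_iter = 300` iterations.
- **Boundary refinement.** After each restart converges, a single-point
  boundary pass (in the spirit of Hartigan–Wong, the default algorithm of
  R's `kmeans`) moves one value across an adjacent cluster boundary whenever
  the move — accounting for both centroid updates — lowers the WCSS. This
  acceptance condition is strictly stronger than Lloyd's nearest-centroid
  stability and escapes the Voronoi-stable local optima that survive
  restarts on flat data.

Optimal 1-D clusters are contiguous in sorted order, so the global optimum
is computable exactly: `kmeans_1d_exact` runs an O(k·n²) dynamic program
over segment boundaries using prefix sums (ties between boundary positions
resolve leftmost). It is the package's verification oracle: for any input
the restarted Lloyd WCSS is bounded below by the DP optimum, and the test
suite checks equality on 500 random small instances.

**Model selection.** The gap statistic follows the standard formulation
with a uniform reference on [min, max] of the observed risks:
`gap(k) = mean_b log W*_kb − log W_k` over `B = 100` reference draws,
`s_k = sd_b(log W*_kb)·√(1 + 1/B)`. Reference fits use 10 restarts (they
are featureless and easy); observed fits use the full 50. The selection
report also records the WCSS elbow and the silhouette (|·| distance;
singleton clusters score 0), Calinski–Harabasz `(B/(k−1))/(W/(n−k))` and
Davies–Bouldin `mean_i max_j (s_i+s_j)/d_ij` indices, all implemented per
definition. Selection strategies: `gap_max` (argmax), `gap_1se` (smallest k
with `gap(k) ≥ gap(k+1) − s_{k+1}`), and `manual`. The pipeline default is
`manual` with k = 4 — cluster count is ultimately a judgment balancing
parsimony against clinically meaningful risk distinctions — with the full
report persisted alongside so the choice is auditable.

## Block coverage

Codes map to WHO blocks by their first three characters, compared
lexicographically against the packaged table of inclusive block ranges
(`src/edrisk/data/icd10_blocks.csv`, a hand-assembled rendering of the WHO
ICD-10 block list without the U chapter; callers may substitute their own).
Blocks are ranked by presentation count (ties alphabetical, for
determinism); `blocks_at_threshold(t)` is the smallest number of top blocks
whose cumulative share reaches t. Dominance uses ≥ 75 % (the comparison is
`≥`, and the representation basis is presentations; a code-level basis can
be derived from the same summaries). Unmapped codes are a hard error by
default, or collected into an `UNMAPPED` pseudo-block under the permissive
policy. Both pre- and post-filter block counts are observable (the filter
report lists excluded codes; block summaries count what remains).

## Proportional-odds model

Cumulative-logit with common slopes: `logit P(Y ≤ j | x) = θ_j − βᵀx`,
j = 1..k−1. The orientation is chosen so that a positive coefficient (OR
above 1) means higher odds of membership in a *higher-risk* cluster.
Fitting is full Newton–Raphson on (θ, β) with analytic gradient and
Hessian, initialised at β = 0 and θ at the empirical cumulative logits.
Steps are halved (up to 40 times) until the log-likelihood does not
decrease and the thresholds stay strictly increasing, making the likelihood
path monotone. Convergence is declared when the gradient max-norm falls
below `tol·max(1, |loglik|)` with `tol = 1e-8`: the scaling keeps the
criterion attainable at n ~ 10⁵, where floating-point accumulation noise in
a likelihood of magnitude 10⁵ exceeds an absolute 1e-8. Divergence of any
coefficient beyond |30| raises a separation error. Wald 95 % intervals are
`exp(β ± 1.96·se)` from the observed information; the forest table rounds
ORs and CIs to 2 decimals (half-up, like all reported percentages).

Reference levels (configurable): female sex, Chinese ethnicity (the modal
category), normal vitals, no comorbidity. Counts of prior encounters enter
untransformed per unit; age in years untransformed. No proportional-odds
(Brant-type) diagnostic is computed. The implementation was cross-checked
against an independent ordinal-regression implementation (statsmodels
`OrderedModel`) in the test suite; the library is never used in the fitting
path.

## Synthetic registry: what it emulates, and what it does not

The generator reproduces the structure of an ambulatory (triage classes
3–4) tertiary-ED cohort:

- **Code universe.** 510 codes sampled from 3-character WHO prefixes
  (external-cause chapters excluded; 40 % carry a 4th character), assigned
  to four latent risk tiers with code counts proportional to 262/104/66/78.
  Baseline risks are Beta(c·s, (1−c)·s) around tier centres
  (0.047, 0.195, 0.478, 0.78) with spread s = 200 by default (within-tier
  sd ≈ 0.015–0.035); s = ∞ degenerates to exact centres.
- **Frequencies.** Zipf weights (`rank^−1`, ranks permuted over codes),
  rescaled so tier totals match presentation shares 61/20.6/12.9/5.5 % —
  low-risk diagnoses are disproportionately *common* in such cohorts, and
  this rescaling is what pins the expected marginal admission rate at the
  share-weighted 17.3 % (per-seed realisations vary by a few points because
  a handful of codes carry much of the Zipf mass). Setting
  `tier_presentation_shares=None` gives plain permuted-Zipf weights.
- **Covariates.** Age ~ N(46.2, 19.4²) truncated to [0, 110]; sex 46.6 %
  female; ethnicity 58.4/15.5/12.2/13.9 % Chinese/Indian/Malay/Others;
  vitals normal with sbp ~ N(127.4, 12.1²), pulse ~ N(82.3, 12.4²),
  temp ~ N(36.69, 0.58²) — chosen so the categorical prevalences match an
  ambulatory case mix (hypotension 0.1 % / hypertension 41.4 %, bradycardia
  3.6 % / tachycardia 26.7 %, hypothermia 2 % / hyperthermia 8.1 %); a CCI
  score pmf giving none/mild/moderate/severe = 81.9/11/3.8/3.4 %; Poisson
  prior-encounter counts with means 0.6 (ED), 0.2 (inpatient), 0.05
  (surgery), 0.01–0.08 (ICU/HD/ICA/infectious).
- **Admission.** `logit p = logit(r_code) + Σ_f β_f (x_f − x̄_f)` with
  default effects at reported OR magnitudes (CCI mild 2.55 / moderate 3.50 /
  severe 5.28, tachycardia 1.46, hyperthermia 2.32, recent surgery 1.31,
  inpatient 1.16, prior ED 0.86, ICU 0.85, HD 0.85). Features are centred
  at their sample means so each code's marginal admission rate stays at its
  nominal baseline (up to a small Jensen gap from averaging on the logit
  scale).

All randomness flows from the single config seed through named
`default_rng` streams; regeneration is bit-identical.

Deliberate non-features: covariates are independent of *which* code a
patient presents with, so in registry-wide ordinal fits the
cluster-membership ORs are near 1 (the generator provides recoverable
ground truth for the admission model and the tier structure separately;
data carrying real covariate–cluster association must be simulated directly
from the proportional-odds model, as the recovery tests do). There is no
secondary-diagnosis structure, no COVID-era case-mix shift, no look-back
window mechanics (prior counts are drawn directly), and no triage-scale
assignment. Passing tests therefore demonstrate correctness of the
*machinery* under the assumed structure — not that real EDs have four
tiers, nor that real covariate effects equal the calibrated magnitudes.

## Problem sizes and determinism

The test suite and the acceptance script use the sizes the analyses are
designed for: a 200,000-presentation registry over 510 codes for
end-to-end tier recovery (adjusted Rand ≥ 0.95, averaged over 10 seeds at
spread 500), 500 random instances (n ≤ 12, k ≤ 4) for exact-oracle
equivalence, 200 instances for per-definition index verification, n = 10⁵
for single-fit OR recovery and 200 × n = 20,000 replicates for CI coverage.
Every stochastic routine takes an explicit seed; the pipeline manifest
records per-stage record counts (input = kept + excluded at every stage)
and re-running a config+seed reproduces byte-identical outputs.

## Known limitations

- The WHO block table is a static fixture; ICD-10-CM dialect differences
  beyond the 3-character prefix are out of scope.
- The exact DP oracle is O(k·n²): intended for code-scale inputs (hundreds
  to thousands of points), not presentation-scale.
- The proportional-odds fitter assumes full-rank designs and detects only
  gross separation (coefficient divergence); near-separation manifests as
  slow convergence with large standard errors.
- Imputation is single-pass mean/median/mode, appropriate only for the
  trivial missingness the pipeline contracts assume (vitals and
  demographics); records without a primary diagnosis or outcome are
  dropped, not imputed.
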