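# Methods

This note documents the models and procedures implemented in `bsetrial`,
the assumptions behind them, the numerical choices, and what the synthetic
data generators do and do not emulate.

## Cluster projection

Diabetes subtypes (MARD-, SIRD-, MOD-, SIDD-like) are defined by k-means on
five continuous clinical features — BMI (kg/m²), age (years), fasting
glucose (mmol/l), C-peptide (nmol/l), HbA1c (mmol/mol). GADA, a binary
feature of the original subtype model, is uniformly negative in a
prediabetes population screened for type 1 diabetes and is excluded: a
constant feature contributes nothing to Euclidean distance and breaks
z-scoring.

Because the features carry incommensurable units, each is z-scored by the
reference cohort's mean and SD, and the identical transform is applied to
trial participants before any distance computation. z-scoring is the
minimal defensible scaling choice for "relative coordinates"; it is
configurable via `FeatureSpec.transforms`.

The projection is a bootstrap: the canonical model is k-means on the full
standardized reference (Lloyd's algorithm, greedy k-means++ initialization,
10 restarts, relative tolerance 1e-6, max 300 iterations — sklearn's
implementation, seeded); then each of B rounds subsamples ⌊0.6·n⌋ reference
rows without replacement, re-clusters, and matches round centroids to the
canonical ones by minimum-cost bipartite (Hungarian) matching on Euclidean
cost. Without matching, per-round labels are arbitrary and counts would be
meaningless; Hungarian matching is optimal and deterministic. Canonical
centroid order is lexicographic over the standardized coordinates, a rule
independent of k-means label arbitrariness. Nearest-centroid ties break to
the lowest canonical index and are logged.

B defaults to 1,000 (score granularity 1/B); k defaults to 4, the
GADA-negative subtypes, even though only three clusters are occupied at the
trial's case mix — the SIDD-like component exists in the reference mixture
but receives ~no trial participants.

One property worth stating precisely: the alignment score does **not**
collapse to 1/k as cluster separation goes to zero. Matching each round's
centroids back to the canonical ones keeps the partition geometry
consistent across rounds, so even for structureless data only participants
near cell boundaries flip clusters. The score is therefore a measure of a
participant's distance from assignment boundaries, which is what makes it
informative; the test suite asserts the monotone degradation with
separation rather than a 1/k limit.

## Response models

The outcome scale is the week-12 − baseline glucose change (`d_glucose`);
glycaemic *improvement* is its negative. The primary model is OLS of
`d_glucose` on treatment, baseline BMI, and baseline HOMA-IR. The HOMA-IR
covariate is deliberately the **baseline** value: the within-trial *change*
in HOMA-IR contains the outcome glucose and is a post-treatment mediator —
conditioning on it absorbs part of the treatment effect itself (roughly
halving a uniform effect in simulation). The change-covariate reading
remains available (`homa_covariate="change"`) as a sensitivity analysis.

Subgroup heterogeneity is assessed with `d_glucose ~ treat * C(cluster)`;
the joint Wald test of the interaction terms is the headline p-value and
per-cluster BSE-minus-placebo contrasts come from linear combinations of
the coefficients. Groups present in only one arm are dropped with a
warning. The BT2160 model regresses the BSE-arm `d_glucose` on log operon
abundance, a MARD-vs-other indicator, their interaction, and Du Bois body
surface area. Zeros in abundance get a pseudocount of half the smallest
nonzero value before the log.

Responder status is inclusive (improvement ≥ 0.3 mmol/l, or ≥ the 75th
percentile in quantile mode); remission is strict (week-12 glucose
< 6.1 mmol/l). The remission regression defaults to a linear probability
model because its plain R² is the quantity of interest; logistic with
McFadden pseudo-R² is the alternative. The median split on BT2160 sends
ties (the median element itself) to the lower stratum. No multiplicity
adjustment is applied anywhere by default; a Benjamini–Hochberg utility is
provided for explicit use.

Analysis population: completers only ("full analysis set" — participants
with post-randomization clinical measures); no imputation.

## Microbiome statistics

Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) is computed with
scipy; it is a semimetric (no triangle inequality), which is why principal
coordinates can produce negative eigenvalues. PCoA is classical scaling:
double-centre the Gower matrix −½JD²J, eigendecompose, scale eigenvectors
by √λ; negative-eigenvalue axes are reported but dropped from coordinates.

PERMANOVA is one-factor: pseudo-F from within/between sums of squared
distances, p = (1 + #{F* ≥ F})/(1 + m) over m seeded label permutations.
The add-one convention means p is never 0 and matches the behaviour of the
standard community-ecology implementation. The gene-abundance permutation
test uses the difference in group means, two-sided on |difference| by
default (sidedness configurable), and reports both the add-one p and the
literal proportion of permuted statistics at least as extreme. Both tests
switch to exhaustive enumeration of all label arrangements for small
samples (n ≤ 8), where the exhaustive proportion is exact and needs no
add-one correction. Ties count as ≥ (inclusive). Repeated-measures designs
are out of scope for the PERMANOVA (one factor only).

Gene richness is the count of features above a detection threshold
(default 0, raw); no rarefaction is applied by default since the inputs
are relative abundances.

## Serum sulforaphane mixture

Post-treatment serum sulforaphane is modelled as a two-component Gaussian
mixture with a **common** variance — the equal-variance constraint reflects
the single spread parameter evident in the bimodal concentration data and
halves the variance parameters EM must estimate. EM is initialized by
seeded 1-D 2-means, updates weights/means in closed form and pools one
variance across components, stops when the log-likelihood gain < 1e-8
(max 500 iterations), and reports components in ascending-mean order. An
SD floor of 1e-4 nmol/ml guards against the point-mass likelihood blow-up.
High/low classification defaults to the posterior-responsibility rule
(high iff P(high | x) > 0.5), which reduces to the midpoint rule under
equal weights and equal variances; boundary values go to "low". The
separation index (μ₂ − μ₁)/σ is ≈ 2 at the preset parameters.

At n = 2,000 and separation 2σ, the sampling SD of each EM component-mean
estimate is ≈ 0.035–0.04 nmol/ml — about three times the known-label SE of
σ/√(n/2) ≈ 0.012, the price of label uncertainty. The acceptance script
therefore averages the recovered means over 15 independent draws rather
than trusting one draw; the per-dataset bias is separately bounded (< 0.02)
in the test suite over 200 datasets.

## Power design

The design statement — 80% power for a 0.3 mmol/l effect at change-score
SD 0.63 and α 0.05, "at least 74 participants" — is reconciled only by a
**one-sample change-score test per arm**: the noncentral-t power of that
design at n = 35/arm is ≈ 0.78–0.80 and the minimal n per arm at 80% power
is 37, i.e. 74 in total. A two-sample test at the same numbers yields only
≈ 0.51 power and would need ≈ 70 per arm. Both designs are implemented;
one-sample-change is the default. Analytic power uses the noncentral-t
(exact for normal data, correct at small n), and the Monte Carlo route
simulates change scores and applies the actual t-test; the two agree within
Monte Carlo error on a parameter grid in the test suite.

## Synthetic data: what is emulated, and what is not

The generators reproduce the trial's published *summary structure*, not its
participants:

* **Reference cohort**: a four-component Gaussian mixture over the five
  clustering features. The true reference centroids are unpublished; the
  preset centroids are plausible values consistent with the qualitative
  cluster descriptions (MARD: older, lower BMI and insulin; SIRD: high
  BMI/C-peptide/insulin; MOD: high BMI, younger, moderate resistance;
  SIDD: insulin-deficient, high HbA1c) and are configuration, not claims.
  Reference mixing weights default to 0.40/0.22/0.22/0.16.
* **Trial cohort**: cluster mix frozen at the observed 51/19/19
  (MARD/SIRD/MOD of 89); cluster feature means chosen once so the mixture
  means match the baseline table (glucose 6.4, BMI 32.1, insulin 18.9,
  C-peptide 1.22); improvement = baseline − week12 ~
  Normal(0.1 + arm·effect(cluster), 0.63), with the placebo drift 0.1
  chosen so the BSE arm's mean glucose moves 6.4 → 6.1. The
  `trial_table1` preset carries the cluster-specific effect (0.4 in
  MARD-like only); `uniform_effect` applies 0.2 everywhere. Non-positive
  draws of positive-valued variables are resampled (truncated normal) and
  logged.
* **Serum sulforaphane**: equal-variance mixture with means 0.2 and
  1.3 nmol/ml and common SD 0.55 = (1.3 − 0.2)/2, i.e. modes two common
  SDs apart, equal weights. The exact mixture is sampled (no truncation at
  zero) so that component-mean recovery is well defined; a `truncate`
  option rejection-samples non-negative values but shifts the low
  component's mean upward by construction. Synthetic concentrations can
  therefore be slightly negative — a deliberate idealization.
* **BT2160**: relative abundance is lognormal (σ_log 0.5) within each
  latent sulforaphane stratum, with stratum means exactly 0.032 (high) and
  0.022 (low). Dependence on improvement exists only in MARD-like BSE
  recipients, induced by a Gaussian copula on the latent normal scale and
  **rank-calibrated**: the copula coefficient is solved numerically
  (Brent's method on a fixed-seed 200,000-point calibration sample, cached)
  so the population Spearman correlation hits the preset target (−0.47).
  The `stratified_bt2160` preset instead uses a single lognormal marginal
  (abundance not differing between clusters) with the copula coefficient
  set analytically to ρ = 0.35/(0.63·√(2/π)), so that among BSE recipients
  the above-median-abundance MARD-vs-other improvement contrast is
  0.35 (base effect difference) + 0.35 (dependence term) = 0.7 mmol/l and
  the below-median contrast is ≈ 0. Remaining features are lognormal noise
  closed to sum 1 − BT2160 per sample, so tables are exactly compositional.
* **Latent ground truth** (true cluster, true sulforaphane component,
  true improvement) is returned in a separate frame and never written by
  the table writers — a leakage guard asserted in the tests.

Not emulated: within-participant correlation beyond the baseline-anchored
change score; measurement error and assay floors; informative dropout
(dropout is independent Bernoulli, default 0); real taxa or phylogenetic
structure in the non-BT2160 features; seasonal/centre effects. Passing
tests therefore demonstrate that the *pipeline* recovers known structure
under idealized sampling — not that the trial's biological conclusions
generalize.

## Numerical conventions

* Missing values are empty CSV cells and NaN in memory; never sentinel
  numbers.
* All stochastic stages accept a seed and are bitwise reproducible;
  bootstrap rounds draw per-round seeds from a single `numpy` Generator.
* Floats are written with repr round-trip precision; write → read is
  value-identical.
* Units are the trial's throughout (glucose mmol/l, insulin mIE/l,
  C-peptide nmol/l, HbA1c mmol/mol, TG mmol/l, GGT μkat/l, sulforaphane
  nmol/ml); the fatty liver index converts TG to mg/dl (×88.57) and GGT to
  U/l (×60) internally because its source formula requires them.
* HOMA values are the closed-form (HOMA1) expressions; externally computed
  HOMA2 values can be supplied as columns instead. The closed form applied
  to the cohort-mean glucose and insulin reproduces the published
  cohort-mean HOMA-IR, which is why it is the computable default.
* The default food-frequency scoring map is a synthetic stand-in (one
  point per recommended category across nine items) preserving the 0–9
  contract; the instrument's exact indicator mapping is not public and the
  map is replaceable configuration.

## Problem sizes

Tests run the large-sample calibration checks at 100,000 simulated
participants (arm or cohort as appropriate), the type-I-error suites at
2,000 replicates of n = 60 trials, permutation-test nulls at 99–500
permutations × hundreds of replicates, and the bootstrap-projection
recovery at a 4,000-row reference with B = 200 rounds; these sizes put
Monte Carlo error well inside the asserted tolerances while keeping the
whole suite around a minute of CPU. The acceptance script uses the same
100,000-scale cohorts and 20,000 power replicates.

## Known limitations

* PERMANOVA is one-factor; no strata/repeated-measures permutation.
* The linear probability model can fit probabilities outside [0, 1]; it is
  kept because its R² is the reported quantity, with logistic as the
  sensitivity option.
* The equal-variance EM is a 1-D special case by design; it is not a
  general mixture toolkit.
* Cluster naming (which canonical centroid is "MARD-like") is a
  user-supplied labelling or a majority vote against latent labels in
  synthetic settings; with real data it requires inspecting centroid
  profiles.
* The bootstrap projection quantifies assignment stability, not cluster
  validity: a stable assignment to a poorly chosen k is still stable.
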