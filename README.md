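# bsetrial

Stratified treatment-response analysis for a randomized, placebo-controlled
trial of broccoli sprout extract (BSE) in prediabetes (impaired fasting
glucose, 6.1–6.9 mmol/l). BSE delivers glucoraphanin, which gut bacteria
carrying the BT2160 operon convert to sulforaphane, a suppressor of hepatic
gluconeogenesis. The package implements the trial's analysis pipeline as a
tested, reusable library and exercises it end-to-end on synthetic cohorts
calibrated to the trial's published summary statistics — the
participant-level data are not public.

## What it does

**Patient stratification** (`bsetrial.clustering`). Participants are
projected onto data-driven diabetes subtypes (MARD-, SIRD-, MOD-, SIDD-like)
by bootstrap k-means: features (BMI, age, fasting glucose, C-peptide, HbA1c)
are z-scored against a reference cohort; in each of B rounds, 60% of the
reference is re-clustered, round centroids are matched to the canonical ones
by Hungarian matching, and each participant goes to the nearest centroid in
standardized Euclidean space. The cluster alignment score
max(counts)/B ∈ (0, 1] measures assignment stability.

**Clinical indices** (`bsetrial.indices`). Closed forms used throughout:
HOMA-IR = G·I/22.5 and HOMA-B = 20·I/(G − 3.5) (G mmol/l, I mIE/l); the
fatty liver index FLI = 100·e^L/(1+e^L) with
L = 0.953·ln TG[mg/dl] + 0.139·BMI + 0.718·ln GGT[U/l] + 0.053·waist − 15.745;
Du Bois body surface area 0.007184·kg^0.425·cm^0.725; the fasting
C-peptide-to-insulin ratio (insulin clearance); IPAQ MET-minutes/week; a 0–9
food-frequency adherence score.

**Response models** (`bsetrial.response`). OLS of the 12-week glucose change
on treatment adjusted for baseline BMI and HOMA-IR; ANCOVA; treatment ×
cluster and BT2160 × cluster interaction models (the latter BSA-adjusted);
pronounced-responder (reduction ≥ 0.3 mmol/l) and remission (week-12 glucose
< 6.1 mmol/l) classification; median-stratified cluster contrasts; a linear
probability model of remission on log BT2160 and GGT.

**Microbiome statistics** (`bsetrial.microbiome`). Bray–Curtis
dissimilarity, principal coordinates (classical scaling), one-factor
PERMANOVA (pseudo-F, seeded permutations, exhaustive for tiny n), the
two-group permutation test for gene abundance, gene richness, and a
within-group dispersion-change test.

**Serum mixture** (`bsetrial.mixture`). Equal-variance two-component
Gaussian EM for the bimodal post-treatment serum sulforaphane concentration,
with posterior high/low classification and a separation index
(μ₂ − μ₁)/σ ≈ 2 at the trial's values.

**Power design** (`bsetrial.power`). Noncentral-t and Monte Carlo power for
one-sample change-score and two-sample designs. At δ = 0.3 mmol/l,
σ = 0.63 mmol/l, α = 0.05 the one-sample design needs 37 per arm — 74
participants in total.

**Synthetic data** (`bsetrial.simulate`). Generators for the reference
cohort, the trial cohort, microbiome tables and serum concentrations, with
presets calibrated so large-sample statistics reproduce the published
numbers (baseline glucose 6.4 mmol/l; change SD 0.63; MARD-specific effect
0.4 and overall effect 0.2; BT2160 stratum means 0.032/0.022; Spearman
−0.47; mixture means 0.2/1.3). See `docs/methods.md` for what the
generators do and do not emulate.

## Worked example

Simulate a trial at the published scale (44 BSE / 45 placebo), project
participants onto the reference clusters and fit the endpoint models:

```bash
bsetrial report --preset trial_table1 --seed 5 --out-dir out
```

prints

```json
{
  "n": 89,
  "primary_estimate": -0.2242494820800804,
  "primary_ci": [-0.465219086812999, 0.016720122652838232],
  "primary_p": 0.0677434310686021,
  "interaction_p": 0.07693577448869894,
  "mean_alignment_score": 0.9947191011235955,
  "cluster_sizes": {"cluster_1": 50, "cluster_2": 26, "cluster_3": 13}
}
```

The primary estimate is the adjusted BSE-minus-placebo difference in the
12-week glucose change: −0.22 mmol/l here, i.e. a 0.22 mmol/l larger
reduction under BSE, not conventionally significant at this n (p = 0.068) —
at trial scale a true overall effect of this size is underpowered, which is
exactly the heterogeneity argument for the cluster analysis. Three of the
four reference clusters are occupied (50/26/13), and the mean alignment
score of 0.99 says the bootstrap assignments are stable. The same stages are
available separately (`simulate`, `indices`, `cluster`, `respond`,
`microbiome`, `mixture`, `power`); every stochastic stage takes `--seed` and
logs it with a config hash.

Fitting the serum sulforaphane mixture on the same synthetic cohort
(`bsetrial mixture --values sulf.csv --seed 5 --out-dir mix`) returns
component means 0.246 and 1.306 nmol/ml with separation 2.8 at n = 44 — the
bimodal structure that separates efficient glucoraphanin converters from the
rest.

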