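# Methods

This document records the statistical model, the default parameters and
why they were chosen, and the numerical design decisions behind
`plasmacohort`. Units are log2 intensity unless stated otherwise.

## 1. Data model

A cohort dataset is an `AnalysisBundle`:

- `quant` — precursor × sample quantity matrix (`QuantMatrix`, which
  carries `scale` ∈ {linear, log2}, `level` ∈ {precursor, protein} and a
  stage log so processing order can be enforced);
- `meta` — per-precursor metadata (protein group, proteotypic flag,
  charge, missed cleavages, peptide length);
- `samples` — per-sample annotation: `role` (study / pool / blank /
  commercial), plate, well, MS batch, and for study samples the
  covariates sex, age, BMI, fasting state, pregnancy, medications
  (ATC codes with a regular-use flag) and contraceptive-use history.

Pooled QC samples (aliquots of one common pool, several per plate) are
the technical anchor: any variation among them is assay noise.

## 2. Preprocessing

Fixed order, enforced by stage tokens; attempting a stage out of order
raises `StateError`.

**Missingness filter.** Precursors missing in strictly more than 40 % of
study samples are removed. Below that, missingness is mostly
intensity-dependent dropout that kNN can reasonably fill; above it, the
imputed share would dominate the estimate.

**kNN imputation, k = 9, within MS batch.** Neighbours are samples from
the same MS batch (technical drift makes cross-batch neighbours
systematically biased; the validation study shows batch-local kNN beats
per-sample mean imputation in ≥ 95 % of replicates at 10 % masking).
k = 9 balances noise averaging against locality for typical batch sizes
of ~240 runs. Rows still missing after the filter cap fall back to the
row mean.

**log2 transform.** All downstream effects are additive on log2 scale;
a coefficient of 1 is a doubling.

**Intensity-dependent normalization (protein-adjusted M-A loess).** For
each sample against the reference (the per-feature median profile), we
form M = sample − reference and A = (sample + reference)/2 and remove a
smooth technical trend in A. A plain M-A lowess, however, absorbs real
biology: when a noticeable fraction of a small protein panel is truly
regulated in a sample (e.g. a contraceptive user with strong hepatic
protein shifts), the fitted trend picks up both the global mean of those
shifts and their local concentration in A, biasing every null protein by
up to ~0.05 log2 in the opposite direction — enough to create false
positives at cohort n. Robust iterations and trimmed or binned variants
do not fix this because regulated precursors sit well within the
residual spread and contaminate bins sign-coherently.

We therefore fit an additive model by backfitting (4 iterations):

    M = trend(A) + offset[protein],

lowess (span 0.7, interpolation delta = 2 % of the A range for speed) for
the trend, per-protein mean residuals for the offsets, with the offsets
re-centred on their **median** across proteins each iteration. The model
is identifiable because technical trends are functions of A only while
regulation moves all precursors of one protein coherently. Median
centring makes the decomposition favour the trend for shifts shared by
most proteins (true sample-loading differences, which normalization must
remove) and favour the offsets for shifts carried by a minority of
proteins (regulation, which it must not touch). Validation: constant
±0.5 offsets are removed to < 0.01, a slope-0.2 intensity-dependent bias
is flattened below |0.02|, pooled-QC CVs do not increase, and injected
effects pass through unshrunk with at most one false positive per
cohort.

**Plate-effect removal.** Per protein, subtract the plate mean and add
back the grand mean (sum-to-zero offsets weighted by plate size), so
per-protein grand means are preserved to ≤ 1e-10 while plate spread
(injected sd 0.3) shrinks ≥ 95 %.

**Protein summarization (Tukey median polish).** For each protein, the
proteotypic-precursor × sample block is decomposed into overall + row
(precursor) + column (sample) effects by alternating median sweeps
(tolerance 1e-6, ≤ 50 sweeps, effects re-centred after every sweep); the
protein profile is overall + column effects. Median polish is robust to
single aberrant precursors (interference, mis-identification) where a
mean would not be. The implementation is verified against an
independently coded oracle to 1e-8 on random blocks.

## 3. QC and the CV anchor

For each protein, `cv_table` computes the coefficient of variation
(100 · sd / mean, n−1 denominator) over pooled-QC samples and over study
samples on linear-scale abundances (a log2 matrix is back-transformed
first). The pooled CV measures pure technical noise; typical values
after preprocessing are 10–15 %. The `log_sd` threshold mode converts a
CV to the log2 sd implied by a log-normal model,
s = sqrt(log2(1 + (CV/100)²) / ln 2).

`sample_qc_metrics` + `flag_outlier_samples` flag runs whose detected
precursor count, median intensity or pool-correlation are ≥ 5 robust z
below their role's distribution; flagged runs are dropped before
preprocessing.

## 4. Association model

Study samples only; pregnant participants and QC-flagged runs excluded.
Per protein, ordinary least squares of the log2 profile on:

    intercept + sex(F=1) + age_decade + bmi_cat1 + bmi_cat3 + bmi_cat4
    + fasting + hcu

BMI categories use 18.5 / 25 / 30 boundaries with category 2 (normal) as
the reference. `hcu` is 1 if any reported medication's ATC code starts
with G03A or G03H (systemic hormonal contraceptives; irregular use
counts, emergency contraception G02B does not). Constant or collinear
design columns raise `RankError` naming the offending term rather than
silently producing unstable estimates.

**Dual significance rule.** Per model term, p-values are Bonferroni
adjusted across the protein family. A protein/term pair is
`cv_anchored_significant` iff

1. adjusted p < α (default 0.05), and
2. |coefficient| > the protein's pooled-QC CV threshold — either
   `literal` (cv_pool/100, the default: a log2 effect at least as large
   as the fractional technical wobble) or `log_sd` (the log-normal log2
   sd implied by the CV).

Proteins with no pool data (CV = NaN) can never be anchored. The guard
study shows that at n = 4000 effects of 0.05·CV reach statistical
significance 100 % of the time yet are anchored 0 % of the time, and the
null study shows the per-term family-wise error stays near the
Bonferroni target.

**Medication scan.** Every ATC prefix at a chosen level (default 3)
with ≥ `min_users` (default 15) regular users is added, one at a time,
as an extra design column and tested under the same dual rule.

**Sensitivity analysis.** Refitting without the `hcu` term shows its
effects re-appear under sex/age (misattribution); `sensitivity_compare`
reports exactly which proteins become newly significant for which terms.

## 5. HCU analyses

- `subgroup_women_under40`: study women, age < 40 (strict), not
  pregnant; the subgroup model drops the sex term.
- `propensity_match`: logistic propensity on sex/age/BMI/fasting, then
  an **exact** one-to-one assignment (`scipy.optimize.linear_sum_assignment`
  on the |score difference| matrix). Greedy nearest-neighbour matching
  is provably suboptimal on crossing instances; the validation study
  confirms the exact solver is never beaten by greedy or by 1000 random
  pairings.
- `roc_auc`: Mann-Whitney pair counting (ties count ½), identical to
  trapezoidal integration of the empirical ROC curve to 1e-10; for a
  binormal marker with standardized separation d the expected AUROC is
  Φ(d/√2), which the empirical estimate matches within 0.02 at group
  sizes of 275.
- `classify_coc`: maps ATC codes to preparation classes
  (EE = ethinylestradiol combined, BE = natural-estrogen combined,
  P4 = progestin-only, non_oral; priority non_oral > EE > BE > P4 when a
  participant reports several). `coc_subtype_effects` fits the subgroup
  model per class vs never-users.
- `hcu_history_analysis`: current vs previous vs never use as two
  contrasts (`hcu_current`, `hcu_previous`); previous ≈ never indicates
  reversibility.
- `cohort_concordance`: Spearman rank correlation of per-protein effect
  sizes across cohorts; two independently simulated and processed
  cohorts replicate with rho ≥ 0.85 over ~150 proteins.

## 6. Synthetic cohort generator

`simulate_cohort` draws, in order: participants (sex, age, BMI, fasting,
pregnancy, medications with realistic ATC priors, HCU prevalence 38 %
among women under 40), plate/well/batch layout with QC pools, blanks and
commercial references per plate, per-protein baselines (mean 13, sd 1.5),
plate and batch offsets (sd 0.05 each), per-protein biological (median
0.38) and technical (median 0.21 ≈ 15 % CV) variability with log-normal
spread across proteins, injected covariate effects (`EffectSpec`),
precursor structure (2–6 precursors per protein, 85 % proteotypic, fixed
ionization offsets sd 1.0), MNAR + MCAR missingness (logistic dropout
midpoint log2 = 9, slope 1.2; 2 % MCAR) and optional degraded outlier
runs. `GroundTruth` records everything needed to score recovery.
`generate_protein_bundle` produces a protein-level, plate-corrected
matrix directly for method-level studies.

Default sizes (790 study samples / 10 plates / 148 proteins, recovery
studies at 800 / 150 with 30 users) were chosen a priori from power
analysis: with biological sd 0.38 and ~30 users among ~200 subgroup
women, the smallest injected |β| of 0.3 has > 90 % power under the dual
rule while staying within a single-core compute budget.

## 7. Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` seeds; a
  pipeline run is bitwise deterministic given its seed (manifest records
  the input matrix SHA-256).
- lowess uses statsmodels with `delta` interpolation (2 % of the A
  range) — O(n) instead of O(n²) per sample with negligible accuracy
  loss at typical precursor counts.
- The offset backfit assumes regulation affects a minority of proteins;
  if most of the panel truly shifts in one direction in some samples,
  the median centring would attribute part of that shift to the trend
  and shrink it. For targeted panels built around one pathway, use more
  iterations with an external set of anchor proteins instead.
- OLS per protein ignores correlation between proteins; family-wise
  control is per term, not across terms.
- The CV anchor uses the pooled-QC CV as-is; with very few pools per
  plate it is itself noisy, and proteins without pool coverage can never
  be reported.
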