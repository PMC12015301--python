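# plasmacohort

Cohort-scale plasma proteomics analysis: from a precursor-level DIA
quantity report with plate, MS-batch and QC-pool structure to covariate-
and medication-association tables under a QC-anchored significance rule,
with dedicated hormonal-contraceptive (HCU) analyses and a synthetic
cohort generator for end-to-end validation.

## The scientific problem

Population plasma-proteome studies quantify hundreds of proteins across
hundreds to thousands of participants and then ask which proteins track
which participant characteristics — sex, age, BMI, fasting state,
medication use. Two things make this statistically treacherous:

1. **Technical structure dominates raw data.** Samples are processed on
   96-well plates and measured in MS batches; ionization efficiency
   drifts; low-abundance precursors drop out non-randomly. Pooled QC
   samples injected on every plate measure the purely technical
   variability of each protein.
2. **Large n makes everything "significant".** With enough samples, a
   0.02 log2 shift reaches Bonferroni significance while being far below
   what the assay can reproducibly measure. `plasmacohort` therefore uses
   a dual rule: a protein/covariate association is reported only if it is
   Bonferroni-significant **and** its |log2 effect| exceeds that protein's
   pooled-QC coefficient of variation — the effect has to be larger than
   the assay's own technical wobble.

A focal application is hormonal-contraceptive use (ATC groups G03A/G03H),
which in women under 40 produces some of the largest effects in the
plasma proteome and confounds naive sex/age analyses. The package ships
subgroup models, propensity matching with an exact assignment solver,
marker AUROC, estrogen/progestin preparation subtyping, current-vs-
previous-use contrasts and cross-cohort concordance.

Because real cohort data cannot be redistributed, the package includes a
full synthetic cohort generator with known ground truth (injected
effects, plate/batch offsets, missingness mechanism, outlier runs), and a
suite of validation studies (`plasmacohort.studies`) that demonstrate the
pipeline recovers what was injected and nothing else.

## Quick start

```python
from plasmacohort import (CohortConfig, EffectSpec, simulate_cohort,
                          run_preprocess, cv_table, analysis_study_samples,
                          build_design, associate)

config = CohortConfig(n_study_samples=400, n_plates=6,
                      wells_per_plate_study=67, n_proteins=60,
                      effect_specs=[EffectSpec("P0001", "hcu", 1.4)],
                      seed=2024)
bundle = simulate_cohort(config)

protein, log = run_preprocess(bundle.quant, bundle.meta, bundle.samples)
cvs = cv_table(protein, bundle.samples)

study = analysis_study_samples(bundle.samples)
study = study[study.index.isin(protein.samples)]
assoc = associate(protein, build_design(study), cvs)
print(assoc[assoc["cv_anchored_significant"]])
```

On this configuration the table contains exactly the injected effect:
protein `P0001`, term `hcu`, coefficient **+1.20 log2** (truth +1.40;
median-polish summarization over partially missing precursors attenuates
slightly), Bonferroni p = 7.3e-39, pooled-QC CV 14%.

The same run is available from the command line:

```bash
plasmacohort all --seed 2024 --out run/   # simulate -> QC -> associate
plasmacohort report run/                  # PCA + volcano figures
```

or stage by stage: `plasmacohort simulate | validate | preprocess |
associate | hcu | report`. Narrative walkthroughs live in `examples/`:

- `examples/01_cohort_association.py` — simulate, QC, preprocess, PCA
  attribution, association table.
- `examples/02_hcu_deep_dive.py` — HCU subgroup model, propensity
  matching, AUROC, preparation subtypes, use history, cross-cohort
  replication.

## Preprocessing chain

`run_preprocess` applies a fixed-order chain, each stage recorded in the
matrix log and enforced by stage tokens so stages cannot be reordered:

1. drop QC-flagged outlier runs;
2. filter precursors missing in > 40 % of study samples;
3. kNN imputation (k = 9) within MS batch;
4. log2 transform;
5. intensity-dependent (M-A loess) normalization with a per-protein
   offset backfit that protects real regulation from being normalized
   away (see `docs/methods.md`);
6. plate-effect removal with sum-to-zero offsets (per-protein grand
   means preserved exactly);
7. Tukey median-polish summarization of proteotypic precursors to
   protein level.

## Testing and validation

```bash
pytest -q                       # full suite (~6 min single-core)
pytest -q --ignore=tests/test_acceptance.py   # fast unit suite (~30 s)
```

`tests/test_acceptance.py` asserts the scientific properties of the
pipeline on frozen-seed simulation studies: median polish against an
independently coded oracle, end-to-end recovery of injected HCU effects,
family-wise error control under the null, the CV-anchor guard at n=4000,
normalization/plate-correction invariants, kNN vs mean imputation, PC1
attribution, misattribution detection, AUROC vs binormal theory, optimal
matching optimality, and cross-cohort replication.

## Layout

```
src/plasmacohort/   containers, io, simulate, qc, preprocess, pca,
                    associate, hcu, studies, pipeline, cli
tests/              unit + acceptance tests
scripts/            acceptance.py metric report
examples/           narrative walkthroughs
docs/methods.md     statistical methods and design choices
```
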