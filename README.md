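# pedgibbs

Pedigree-based Bayesian animal-model toolkit for ordinal conformation
traits: relationship-matrix algebra, a Gibbs sampler for multi-trait
repeatability models, posterior diagnostics, descriptive prevalence /
factor-screening statistics, and a synthetic-data generator with known
ground truth.

## What it does

- **`pedgibbs.pedigree`** — pedigree validation and topological sorting,
  inbreeding coefficients (Meuwissen–Luo recursion), the dense numerator
  relationship matrix `A` (tabular method), its sparse inverse
  (Henderson's rules with inbreeding) and complete-generation counts.
- **`pedgibbs.simulate`** — study-shaped synthetic datasets: a
  random-mating multi-generation pedigree, breeding values drawn by the
  Mendelian-sampling recursion (`u ~ N(0, A ⊗ Σu)`), repeated records
  with five fixed factors (2/3/4/2/3 levels), a permanent environmental
  effect, per-trait missingness, and optional 0/1/2 discretization.
- **`pedgibbs.model`** — the Gibbs sampler for
  `y = Xb + Zu + Wpe + e` with flat priors on fixed effects and
  variance components (limiting inverse-Wishart full conditionals),
  single-site Gaussian updates for all location effects (numba
  kernels), and data augmentation for missing trait scores.
- **`pedgibbs.posterior`** — draw-wise heritability and genetic
  correlation transforms, Geweke Z, batch-means Monte Carlo standard
  error, HPD intervals and a consolidated report.
- **`pedgibbs.descriptive`** — record-level prevalence tables (per
  class and class 1+2), a baseline-category multinomial-logit screen of
  the non-genetic factors (likelihood-ratio tests), and one-way gait
  comparisons with Tukey–Kramer letters.
- **`pedgibbs.io` / `pedgibbs.cli`** — CSV formats, YAML/JSON run
  configs, and the end-to-end pipeline.

## CLI

```sh
pedgibbs simulate --seed 1 --out sim/            # synthetic dataset
pedgibbs describe sim/phenotypes.csv --out desc/ # prevalence tables
pedgibbs glz sim/phenotypes.csv --out glz/       # factor screen
pedgibbs gait sim/phenotypes.csv --out gait/     # walk/trot comparison
pedgibbs fit sim/phenotypes.csv sim/pedigree.csv \
    --traits trait1 --iterations 20000 --burn-in 5000 --out fit/
pedgibbs report fit/posterior_draws.csv --out rep/
pedgibbs pipeline config.yaml                    # everything from a config
```

Phenotype CSVs have one row per evaluation record: `animal`, the five
factor columns (`gender`, `birth_period`, `stud_criteria`, `age_group`,
`appraiser`; integer levels or canonical labels), optional `walk`/`trot`
scores and per-trait 0/1/2 score columns. Pedigree CSVs are
`animal,sire,dam,birth_year,sex` with empty or `0` for unknown parents.

## Notes on the model

The production sampling protocol is 250,000 rounds with 50,000 burn-in
and every sample saved (`ModelSpec` defaults); tests use shorter chains.
The permanent environmental effect is iid per animal by default; a
pedigree-structured variant is available via
`ModelSpec(pe_covariance="pedigree")`. Fixed effects use reference-cell
coding; any full-rank coding yields the same variance posteriors.
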