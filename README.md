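# phenosel

Phenomic and genomic yield prediction for multi-environment wheat trials.

## The problem

Genomic selection predicts line performance from genome-wide markers, but
yield is dominated by genotype-by-environment interaction (GxE): a model
trained in one trial environment transfers poorly to another. High-throughput
field phenomics — multispectral and hyperspectral vegetation indices, visual
scores, soil conductivity — measures the crop *in* the target environment and
so captures exactly the variation markers cannot. This package implements,
end to end and at desk scale, the study design that compares the two: a large
panel of elite crosses grown at two locations over two years, predicted from
phenomic traits, from markers, and from both.

Because the original field data are proprietary, the package ships a
first-class synthetic-data generator that reproduces the study's structure:

- 44 crosses (39 biparental, 5 three-way) from 27 elite parents, 68 F2:4
  lines per cross, genotyped as pooled DNA of ~6 F4 sibling plants
  (fractional "codominant" dosages), with meiosis under the Haldane map
  function (scaled-down profiles are the defaults);
- four site-year environments with a configurable between-environment
  genetic correlation matrix (defaults follow the study's observed
  0.15–0.39 range) and a modified alpha-lattice layout with unbalanced
  replication summing to 4 plots per line;
- ~110 plot-level traits in ~40 redundancy groups, where spectral
  categories carry most of the yield signal and visual/soil traits almost
  none.

On top of the generator sit the analysis stages: marker QC (mean
imputation, PIC > 0.1 filter, |r| > 0.9 greedy pruning), EM-REML block
variance components and line BLUEs, trait dimensionality reduction
(PCO / PLS), penalized regression (lasso / elastic net / ridge by cyclic
coordinate descent, quadratic penalty 0 / 0.1 / 1), univariate and
multivariate GBLUP on a VanRaden relationship matrix, and a
masking/resampling engine (fraction grids, whole-location leave-out,
training-set supplementation) scored as the squared correlation between
predicted and observed yield.

## The models

Plot yield is simulated as

    y = mu_env + g + block + sub_block + e_cond + e_meas

with per-line genetic values g whose between-environment correlation matrix
is controlled exactly, split into a marker-tracked and a polygenic share.
`e_cond` is plot-condition variation that canopy sensors can see; `e_meas`
is harvest measurement error that they cannot.

Penalized prediction minimises

    (1/2n) ||y - b0 - X b||^2 + lambda1 ||b||_1 + (lambda2 / 2) ||b||^2

by coordinate descent with soft-thresholding (lambda2 = 0 for lasso, 0.1
for elastic net, 1 for ridge; lambda1 by internal cross-validation).
GBLUP solves Henderson's mixed-model equations with G = ZZ' / 2 Σ p(1-p);
the multivariate variant places Gt ⊗ G and Rt ⊗ I over yield plus PCO/PLS
co-responses and predicts masked yields conditionally.

## Worked example

```python
from phenosel.studies import core_finding
print(core_finding(seed=1, n_reps=20))
```

Under the core study conditions (320 lines, four environments, genetic
correlation 0.3 between environments, spectral traits carrying ~60% of the
yield signal), predicting one full location of a year from the other
location prints, for line BLUEs:

```
whole_location_phenomic_r2   0.645
whole_location_genomic_r2    0.058
whole_location_combined_r2   0.648
whole_location_phenomic_plus10pct_r2  0.649
```

Phenomic traits measured at the test location predict its yield an order of
magnitude better than markers trained on another environment (R² 0.645 vs
0.058); combining both adds essentially nothing beyond the phenomic model;
and seeding the training set with a random 10% of the test location nudges
accuracy up further. The same qualitative pattern — high phenomic, low
cross-environment genomic, modest complementarity — is the study's central
result.

The numbered drivers under `analysis/` walk the full study: dataset
simulation, marker QC, BLUEs and observed GxE, trait redundancy (111 traits
collapse to 40 at |r| < 0.9; the first three PCs explain ~51% of panel
variance), within-year fraction grids, whole-location transfer, and
multivariate GBLUP with phenomic co-responses. Each writes its tables under
`results/`. Run them in order from `analysis/` (e.g.
`cd analysis && python 01_simulate_dataset.py`).

A `phenosel` command-line interface wraps the stages (`simulate`, `qc`,
`blues`, `reduce`, `predict`, `run`); `phenosel run --config study.yaml`
executes a full config-driven study reproducibly (identical config + seed
gives bit-identical outputs).

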