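# Methods

This note documents the models, generator assumptions, numerical choices
and known limitations of `phenosel`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

The package reproduces the shape of a large elite-cross wheat yield trial:
crosses from a shared parent pool, selfed to F2:4 and bulk-genotyped;
two locations in each of two years; a modified alpha-lattice layout in
which a replicated core (entries appearing once in each of two blocks, in
sub-blocks of five) is padded with un-replicated entries; and a plot-level
phenomic panel spanning multispectral flights (F1–F5 through the season), a
single post-flowering hyperspectral flight, visual assessment scores
(EARLY/MID/LATE growth stages) and two soil-conductivity depths. The full
replication pattern allocates six line groups so that every line receives
exactly 4 plots across the four environments and every environment holds as
many plots as there are lines; scaled profiles keep those proportions.

## Genetics

Founders are fully homozygous with per-marker allele frequencies drawn
uniformly in [maf_low, maf_high] (defaults 0.2–0.5). Meiosis uses the
Haldane map function with no crossover interference on a wheat-like map of
21 chromosomes x 150 cM; markers are evenly spaced, so linkage
disequilibrium between adjacent markers is mild at the default densities —
correlation pruning consequently removes few simulated markers even though
the QC chain itself is fully exercised (tests construct dense redundancy
explicitly). Three-way crosses are (P1 x P2) F1 crossed to P3 before
selfing. A line's genotype is the mean dosage of `n_plants` (default 6) F4
sibling plants, giving fractional pooled scores; an optional per-call error
rate replaces calls with uniform random genotypes to emulate relaxed
array-QC thresholds (default 2%), and sporadic values are set missing
(default 2%).

## Yield model and GxE

Plot yield is `mu_env + g + block + sub_block + e_cond + e_meas`, with
block and sub-block effects drawn per environment. Defaults (t/ha):
sigma_block = 0.3, sigma_subblock = 0.2, sigma_cond = 0.35,
sigma_meas = 0.5. The genetic variance per environment is set from the
plot-level heritability target, h2 = var(g) / (var(g) + all nuisance
variances), default 0.4.

Genetic values across environments are built from a marker-driven
component (QTL effects drawn with the target between-environment
correlation) plus a polygenic component orthogonalised against it, and the
combined matrix is whitened and recoloured so that the *realized* sample
correlation matrix equals the configured one exactly. This is deliberate:
with a few hundred lines in cross families, the dosage matrix has low
effective rank and raw QTL-effect constructions miss the target
correlations by large random margins. The `marker_share` parameter
(default 0.7) fixes the fraction of genetic variance the assayed markers
can explain; the remainder is untyped background, which caps genomic
prediction accuracy realistically.

The default correlation targets are the study's observed between-location
Spearman values (0.15–0.39). Those published values are correlations of
noisy line means, so applying them at the genetic level makes the
simulated *observed* correlations come out lower (noise attenuation); the
package treats the configuration as a genetic-scale target because every
recovery test and the acceptance study are stated on true genetic values.

The split of the plot residual into a condition component (`e_cond`,
visible to canopy sensors) and a measurement component (`e_meas`,
invisible) is a generator design choice: without it, traits built from the
full yield residual predict plot yield almost perfectly, which no real
canopy measurement does. The split sets the phenomic accuracy ceiling at
roughly var(signal) / (var(signal) + var(e_meas)).

## Trait panel

Each redundancy group owns one latent crop-status variable:
`sqrt(s) * signal + sqrt(1-s) * noise`, where `signal` is the plot's yield
deviation minus measurement error, standardised within environment, and
`s` is the category/time-point signal share. Traits are near-copies of
their group latent (squared loading 0.97) plus independent noise, then
affine-mapped to category-plausible scales. Defaults: 15 multispectral
groups x 3 traits cycling over five flights with signal share rising to
0.60 at mid grain-fill and falling with senescence (0.25, 0.45, 0.60,
0.55, 0.30); 18 hyperspectral groups x 3 at 0.60; 5 visual groups x 2 at
0.05; 2 soil traits at 0. That yields 111 traits in 40 groups, chosen so
correlation pruning at 0.9 collapses the panel to the study's "about 40
distinct traits".

What the generator does *not* emulate: raw reflectance wavebands (traits
enter as computed indices), spatial autocorrelation beyond block effects,
weather-driven dynamics, pedigree structure, and trait-specific
missingness across years. Passing tests therefore demonstrate the
machinery and the qualitative GxE logic, not field-data performance.

## Marker QC

Mean imputation stands in for model-based imputation (the reference
pipeline's haplotype imputation is out of scope). PIC is the biallelic
`1 - (p^2 + q^2) - 2 p^2 q^2` with p estimated as mean dosage / 2 (valid
for pooled fractional scores); the filter is strictly `> 0.1`. Redundancy
pruning is a greedy single pass in map order dropping any marker with
|r| > 0.9 against an already-retained marker; `order="pic_desc"` is offered
because the retained set depends on the walk order, and absolute
correlation is used as the conservative reading of redundancy.

## Mixed models

`em_reml` fits y = Xb + Σ Z_i u_i + e by EM-REML. Each iteration does one
Cholesky factorisation of the mixed-model-equation matrix, from which the
solution, the restricted log-likelihood
(−2lR = (n−p−q) ln s2e + Σ q_i ln s2_i + ln|M| + y'Py/s2e) and the trace
terms of the EM updates all derive. Plain EM steps are interleaved with
component-wise Aitken extrapolations accepted only when the likelihood
does not decrease, so the recorded trace is monotone and convergence
(|Δ loglik| < 1e-8, max 500 iterations) is reached in tens rather than
hundreds of iterations. Variances are floored at 1e-10 x var(y).
Non-convergence returns the last iterate with a warning.

BLUEs are per-environment generalized-least-squares line means given the
REML block/sub-block variances, computed with one factorisation per
environment shared across all responses (yield and every trait). Lines
absent from an environment have no row.

GBLUP uses the VanRaden kernel (monomorphic markers excluded) and the
factorisation u = L a with G = L L', which reduces variance estimation to
the same EM machinery; predictions for unphenotyped lines are
sigma2_g G[:,obs] V^-1 residuals plus the GLS mean. Multivariate GBLUP
estimates trait covariance matrices by eigen-rotating the kernel on the
complete-record lines (per-rotated-row EM on t x t matrices; means removed
per trait first, so the estimate is ML rather than REML — a deliberate
simplification at these sizes) and then holds them fixed for conditional
prediction of masked yields from all observed cells. With diagonal trait
covariances this reduces exactly to the univariate fit, which the tests
assert to 1e-6.

## Penalized regression

The objective is scaled by 1/n so lambda values are sample-size stable;
this matches the convention of standard elastic-net software, and the
lasso/elastic-net/ridge settings (lambda2 = 0 / 0.1 / 1) follow the
study's conventions. The L1 strength is not stated by the study; the
default rule is 5-fold internal cross-validation over a 50-point
log-spaced path from lambda1_max down three decades, warm-started, with a
fixed-lambda1 override for reproducibility-sensitive runs (the evaluation
engine defaults to a 20-point path; the acceptance study uses 12 points to
keep twenty replicates within minutes — a resolution, not a science,
choice). Predictors are standardised on training rows only; responses can
be centred/scaled per location with the inverse stored. For whole-location
prediction the test location's scale is unknown by construction, so
back-transforms fall back to pooled training moments; accuracies are
squared correlations and unaffected.

## Evaluation engine

Units are raw plots or line BLUEs, as parallel tracks. Fraction-grid
schemes sample each environment independently (the grids cross the two
locations' fractions). Whole-location schemes enumerate 3-train/1-test and
the two 2-train variants; supplementation adds a stated random fraction of
the test environment to training. Masks derive deterministically from
(master seed, scheme id, replicate), so every record is reproducible
bit-identically. GBLUP-family methods consume line BLUEs z-scored within
environment and averaged over training environments per line — a
scale-free response the study leaves unspecified — and are scored against
the test environment's z-scores. Pooled summaries weight locations equally
(the "average over both locations" convention); accuracy with a
zero-variance side is defined as 0 and flagged.

## Problem sizes and defaults

The core study conditions are 10 crosses x 32 lines (320 lines), 300
markers, four environments, the full unbalanced replication pattern,
genetic correlation 0.3 between environments, noisy bulk genotypes and the
default trait panel. Parameter-recovery runs use twenty replicates of
1000-plot single-environment trials. These sizes keep the complete test
suite and the acceptance script in the minutes range on one CPU while
leaving every qualitative contrast (phenomic >> genomic across locations,
modest complementarity, supplementation gains, fraction-grid monotonicity)
with comfortable margins.

## Known limitations

- Check varieties are generated and flagged but excluded from prediction
  analyses by default; how the original study handled them is unstated.
- The alpha-lattice randomisation is a simple randomised allocation, not
  an optimal alpha design.
- Multivariate covariance estimation requires a complete-record subset;
  heavy missingness in co-responses is unsupported.
- The CLI's `predict` treats every non-design column of the input table as
  a trait; column conventions follow the simulator's writers.
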