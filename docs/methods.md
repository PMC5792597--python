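# Methods

This note documents the statistical models implemented in `cetadiv`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter when reproducing results.

## Diversity estimation

### Microsatellite (relative nuclear) diversity

Observed allele counts confound four things: the locus's intrinsic
richness, the species' diversity, the number of individuals genotyped,
and ascertainment bias.  The estimation chain separates them.

**Inclusion filters.**  Record-level thresholds first (≥ 2 alleles,
sample size strictly > 5 individuals), then loci used on ≥ 5 distinct
species, then species typed at ≥ 4 distinct retained loci.  The filters
are applied once, in that order, with no fixed-point iteration; a locus
that drops below five species because a species was removed in the last
step is retained.  This single-pass rule is documented here because the
order is a genuine degree of freedom in such pipelines.

**Discovery curve.**  Allele discovery is modelled as
*a*(*n*) = *A*<sub>ℓ</sub> · *n*μ / (1 + *n*μ): a hyperbolic saturation
in the number of individuals *n*, with one asymptote *A*<sub>ℓ</sub> per
locus and a single discovery rate μ (units: per individual) shared by all
loci within a study scope.  The model form is an assumption — it is
exactly the inversion of the correction formula
corrected = observed·(1 + *n*μ)/(*n*μ), and the gene-copy-sampling mode of
the generator confirms it tracks a mechanistic discovery process within
~10 % over *n* ∈ [6, 200].  μ is fitted on *observed* (not corrected)
counts by least squares on the count scale; the per-locus asymptotes are
profiled out in closed form, leaving a 1-D problem in log μ solved by
bounded scalar minimisation (bounds 10⁻⁴–10², tolerance 10⁻¹⁰ on log μ).
A multiplicative-error loss (least squares on logs) is available via
`loss="log"` for data whose noise is clearly lognormal.  When species
differ strongly in diversity, the shared-curve fit absorbs some of that
heterogeneity into μ̂; the downstream species *ranking* is insensitive to
this (the mixed model controls locus and sample-size effects again), but
μ̂ itself should be read as a dataset-level summary, not a biological
constant.

**Mixed model.**  `log(corrected) ~ species + locus + ascertained`, with
species as fixed effects and *no global intercept*, loci as Gaussian
random intercepts, and ascertainment as a binary fixed covariate; fitted
by REML (statsmodels MixedLM, L-BFGS with a Powell fallback).  Species
effects are re-centred to mean zero for reporting so that sign carries
meaning (negative = below the cetacean average); the zero point is a
convention, rankings and contrasts between species are invariant to it.
Boundary estimates (zero locus variance) are allowed.  Exactly collinear
noise-free inputs (residual variance ≈ 0, below 10⁻¹² per record) take a
documented fast path: the fixed effects are solved by ordinary least
squares and both variances reported as zero, since REML is undefined
there.

### Mitochondrial diversity

Per species and scope, π (carried in percent throughout) is the
unweighted arithmetic mean of published estimates with ≥ 100 sequences.
Studies are classed rangewide iff coverage ≥ 25 % of the range
(inclusive) or an entire ocean basin.  No weighting by sample size is
applied — the inputs are heterogeneous published values, not raw data —
and records from the same paper are treated as independent studies.

## Comparative statistics

### Independent contrasts

Felsenstein's pruning recursion: at a node joining child states
(*x*₁, *v*₁), (*x*₂, *v*₂), the standardized contrast is
(*x*₁ − *x*₂)/√(*v*₁ + *v*₂); the node gets the 1/*v*-weighted mean and
its parent branch is lengthened by *v*₁*v*₂/(*v*₁ + *v*₂).  Polytomies
are resolved deterministically before the recursion — children ordered by
the smallest tip label in their subtree, folded left with zero-length
internal branches — so contrasts are reproducible and signs well defined.
Contrast-based correlation is computed through the origin with
F = r²(n−1)/(1−r²) on (1, n−1) degrees of freedom, n the number of
contrasts.  Signs are retained (contrasts are not positivized); compare
|r| against unsigned tabulations.  Zero-variance junctions (both child
branches zero) raise an error unless `allow_zero_length=True`, which
substitutes a floor of 10⁻⁸ × tree depth.

### PGLS

Generalized least squares with error covariance from the tree, fitted by
whitening (Cholesky, or an eigendecomposition shortcut for λ — see
below).  Two correlation structures:

* **Stationary Ornstein–Uhlenbeck**: corr(i,j) = exp(−α·d<sub>ij</sub>),
  d the patristic distance, unit diagonal.  This is the stationary form
  (process at equilibrium around its optimum), matching the
  selective-optimum interpretation; α has units 1/branch-length.
* **Pagel's λ**: Brownian covariance with off-diagonals multiplied by λ,
  diagonal unchanged.  λ = 0 is the star phylogeny (GLS = OLS), λ = 1
  Brownian motion.  λ is allowed below zero down to the tree-specific
  bound at which the matrix loses positive definiteness, computed exactly
  from the eigenvalues of D^(−1/2) C D^(−1/2) (D = diag C); negative ML
  estimates do occur on real comparative data.

The structure parameter is estimated by maximising the *restricted*
likelihood over a 64-point grid (linear in λ over the admissible
interval capped at 1 − 10⁻⁶; logarithmic in α over [10⁻³, 50]/d̄ with d̄
the mean patristic distance) followed by golden-section refinement to
10⁻⁶.  For λ the whole profile costs one eigendecomposition: with
V(λ) = D^(1/2)[(1−λ)I + λM]D^(1/2) and M = QΛQ′, rotating the scaled data
by Q′ turns every V(λ) into a diagonal weight matrix.

Per-term F tests are sequential (type I) in the order the terms are
written, intercept first, with the denominator MSE from the full model —
the convention of standard ANOVA tables for ordered formulas.  A marginal
(type III) alternative was considered and not implemented; with the
small, unbalanced species samples these analyses use, sequential tests
answer the question actually asked ("does the term add signal to what is
already in the model?").

**Boundary λ̂ caveat.**  When λ̂ lands on the lower admissible bound the
covariance is nearly singular along the grand-mean direction and the
intercept's sequential F becomes enormous.  This is correct GLS
arithmetic, not evidence about the intercept; treat such fits as boundary
estimates (the λ̂ value itself remains interpretable).

## Univariate screening

Categorical factors: one-way ANOVA with the classical sums-of-squares
decomposition; effect size Cohen's *d* (df-weighted pooled SD, reported
unsigned) for two observed levels, ω² = (SSB − df₁·MSW)/(SST + MSW)
otherwise.  ω² is not clamped at zero; negative values (F < 1) are
reported as computed.  Continuous factors: independent-contrast
correlation on the tree pruned to complete cases (plain Pearson as a
diagnostic option).  Strong-effect thresholds, strict inequalities:
*d* > 0.8, ω² > 0.14, |r| > 0.4.  Factor × marker pairs with fewer than
5 complete cases, a single observed level, or no residual degrees of
freedom are skipped with a logged reason.  The number of oceans in the
range (ocean1) is treated as categorical by default (it enters ANOVA
tables), with a flag to treat it as quantitative.

## Model selection

Gaussian linear models with dummy-coded categoricals (reference = first
level in sorted order).  AIC uses the *full* Gaussian log-likelihood
(2π constant included) and counts the error variance among the
parameters — the `AIC()`-on-`lm` convention — so values are comparable
with standard statistical software output.  Stepwise search starts from
the null model and at each step evaluates every single-term addition and
deletion, applying the best strictly-AIC-decreasing move; ties prefer
deletions, then lexicographic term order, making paths deterministic.
The species set is frozen to the complete cases over the whole candidate
pool before searching, so every AIC on the path is computed on identical
data.  The default candidate pool excludes the encephalization quotient
and the IUCN population trend (both would shrink the frozen species set
drastically) and the mysticete-only breeding strategy.  After the search,
the parsimony rule picks, among all models visited within Δ = 5 AIC of
the best, the one with fewest terms (ties: lower AIC).  With pure-noise
candidates this two-stage procedure retains the null model in ≫ 85 % of
replicates; plain stepwise alone would not (a single noise predictor
improves AIC with probability ≈ 0.16).

## Synthetic data

The generator emulates the *statistical* structure of a literature
compilation, not its biology:

* **Tree**: pure-birth (Yule), default 42 tips, birth rate 1; ultrametric.
* **Factors**: continuous factors are Brownian latent traits rescaled to
  realistic ranges (log₁₀ population size centred on 10⁵, latitudinal
  ranges ~5–150°, lengths ~1–33 m, …); categorical factors threshold
  latent Brownian traits so they carry phylogenetic signal, as real
  factors do.  Missingness mimics a compilation's coverage (population
  size ~83 % of species, lifespan ~74 %, population trend ~26 %, …).
* **Planted truth**: nuclear species effects are a linear function of the
  population-size latent (slope 0.8 on the standardized scale, residual
  SD 0.2); mitochondrial means are lognormal around 1 % with a
  latitudinal-range effect (slope 0.5) and a matrilineal multiplier
  (default 0.3) applied to 5/42 of species, drawn from the odontocetes
  (clustered on the tree via a latent trait, as the real matrilineal
  species are).
* **Microsatellites**: default 30 loci, asymptotes lognormal around 10
  alleles (log-SD 0.4), μ = 0.2, ascertainment offset 0.1 (each locus
  ascertained on one source species), lognormal count noise SD 0.1,
  samples of 6–200 individuals, counts rounded to integers (a
  `round_counts=False` switch exists for exact noise-free algebra).  A
  `gene_copy_sampling` mode replaces the curve with a mechanistic
  process — a broken-stick allele frequency spectrum sampled 2n gene
  copies deep — used to validate the saturation-model assumption.
* **mtDNA**: 1–4 studies per species, 50–400 sequences (so the n ≥ 100
  filter genuinely bites), lognormal study noise SD 0.15.

Every generator is a pure function of (config, seed).  What the
generator does **not** emulate: real study overlap (shared individuals
across papers), within-species population structure, correlated
missingness, non-neutral loci, mutation-model detail, and non-ultrametric
trees.  Passing tests therefore demonstrate that the estimators recover
the truth under the stated generative assumptions — they cannot certify
behaviour under violations the generator does not produce.

## Problem sizes used in validation

Calibration and recovery checks run at: discovery-rate recovery 50
replicates of 30 loci × 40 species; contrast variance 500 Brownian
replicates on a 200-tip tree; contrast-correlation type-I error 2000
replicates on 28-tip trees; λ recovery 200 replicates on a 100-tip tree;
greedy-vs-exhaustive stepwise 200 replicates of 4 candidates at n = 40;
end-to-end recovery 50 independent 40-species studies.  The full
42-species pipeline itself runs in about a second.

## Known limitations

* μ̂ is biased when species heterogeneity is large (see above); the
  species ranking is robust to this but the printed μ is condition-bound.
* The mixed model treats replicate studies of the same species × locus as
  independent; duplicated records leave point estimates unchanged but
  overstate precision.
* Sequential F tests depend on term order; callers choose the order.
* OU and λ structures are fitted on the correlation/covariance scale with
  a single overall variance; no measurement-error ("lambda-on-residuals
  vs traits") distinction is modelled.
* ω² can be negative and is reported as such; consumers expecting a
  clamped effect size must clamp downstream.
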