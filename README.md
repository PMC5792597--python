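# cetadiv

What shapes genetic diversity across cetacean species?  `cetadiv` is a
comparative-analysis toolkit for answering that question from
literature-compiled data: per-study microsatellite allele counts, published
mitochondrial control-region nucleotide diversities (π, in %), a table of
candidate predictor factors (population size, IUCN status, whaling history,
taxonomy, range, habitat, body size, life history, brain size, social
structure), and a dated phylogeny.  It is written for comparative and
population geneticists who want the full chain — per-species diversity
estimation, univariate screening, and multivariate model selection with
phylogenetic correction — as tested, reusable library code rather than a
one-off analysis script.

## The methods at its core

**Relative nuclear diversity.**  The number of alleles observed at a
microsatellite locus depends strongly on the number of individuals
genotyped.  Allele discovery is modelled as a saturating curve
*a*(*n*) = *A*<sub>ℓ</sub> · *n*μ / (1 + *n*μ) with per-locus asymptotes
*A*<sub>ℓ</sub> and a single per-individual discovery rate μ fitted by least
squares; inverting it gives the sample-size correction
corrected = observed · (1 + *n*μ) / (*n*μ).  Log corrected counts are then
decomposed by a REML linear mixed model,

    log(corrected) ~ species (fixed) + locus (random) + ascertained (fixed),

and the centred species effects are the relative nuclear diversity: a value
below zero means fewer alleles than expected of an average cetacean after
controlling for sample size, locus, and ascertainment bias (loci are richer
in the species they were developed on).  Records pass inclusion filters
first: ≥ 2 alleles, > 5 individuals, loci used on ≥ 5 species, species
typed at ≥ 4 loci.

**Mitochondrial diversity.**  Per species and study scope, π is the
unweighted mean of published estimates based on ≥ 100 sequences.  Studies
are *rangewide* when samples cover ≥ 25 % of the range or an entire ocean
basin, *regional* otherwise, giving four markers: πR, πO, micR, micO.

**Comparative statistics.**  Continuous predictors are tested with
Felsenstein's independent contrasts (through-origin correlation of the
standardized node differences); categorical predictors with one-way ANOVA
plus Cohen's *d* (two levels) or ω² (more), flagged strong at *d* > 0.8,
ω² > 0.14, |*r*| > 0.4.  Multivariate models are chosen by bidirectional
stepwise AIC with a parsimony rule (simpler models win within ~5 AIC
units) and confirmed by phylogenetic generalized least squares with a
stationary Ornstein–Uhlenbeck correlation exp(−α·*d*<sub>ij</sub>) or
Pagel's-λ covariance, the structure parameter estimated by restricted
maximum likelihood (λ may go below zero down to the tree's
positive-definiteness bound).

A synthetic-data generator produces ground-truthed studies with the same
statistical structure — a Yule tree, factors evolving on it, saturating
allele counts, noisy per-study π, and a matrilineal flag that depresses
mitochondrial diversity — so every stage can be validated against known
truth.

## Worked example

```python
import cetadiv as cd

bundle = cd.simulate_study(cd.SimulationConfig(seed=7))
estimates, correction, mixed = cd.estimate_relative_diversity(
    bundle["msat_regional"], return_fits=True)
print(f"mu = {correction.mu:.4f}")
lowest = min(estimates, key=lambda e: e.value)
print(f"lowest: {lowest.species_id} {lowest.value:+.3f}")
```

prints

```
mu = 0.2768
lowest: S0040 -1.805
```

— the fitted discovery rate (≈ 0.28 new alleles per extra individual at
small samples for this realization) and the species whose nuclear
diversity sits lowest relative to the cetacean average: exp(−1.8) ≈ one
sixth of the expected allelic richness.  `examples/` walks through each
capability the same way: simulation, nuclear and mitochondrial
estimation, independent contrasts, and model selection with PGLS.  On the
default synthetic study, model selection recovers the planted structure —
population size drives nuclear diversity, latitudinal range and the
matrilineal flag drive mitochondrial diversity.

A thin CLI wraps the pipeline:

```bash
cetadiv simulate --seed 7 --out study/
cetadiv run-all --config config.yaml --seed 7 --out results/
```

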