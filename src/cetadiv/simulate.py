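"""Synthetic comparative datasets with known ground truth.

The generator emulates the statistical structure of a literature-compiled
cetacean diversity study: a pure-birth (Yule) phylogeny; continuous and
categorical species factors evolving on that tree (categoricals by
thresholding latent Brownian traits, so they carry phylogenetic signal as
real factors do); a microsatellite study table whose allele counts follow
a saturating discovery curve in sample size with lognormal noise,
locus-specific asymptotes, species effects and an ascertainment offset;
and an mtDNA study table of noisy per-study pi values around species
means.  A binary matrilineal factor depresses the mitochondrial means of
a configurable fraction of species, the pattern the analysis is meant to
recover.

Defaults mirror the compiled study's conditions: 42 species, 30 loci,
discovery rate mu = 0.2, ascertainment offset 0.1 on the log scale,
lognormal count noise sd 0.1, sample sizes 6-200 individuals, mtDNA study
sizes 50-400 sequences (so the n >= 100 inclusion rule bites), five of 42
species matrilineal with mitochondrial diversity reduced to 30%.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .comparative import lambda_covariance, ou_correlation
from .errors import DomainError, ValidationError
from .records import MicrosatRecord, MtdnaRecord, SpeciesFactors
from .tree import Node, PhyloTree

__all__ = [
    "TraitModel", "MsatSpec", "MtdnaSpec", "SimulationConfig",
    "simulate_yule_tree", "simulate_trait", "simulate_msat_dataset",
    "simulate_mtdna_records", "simulate_factor_table", "simulate_study",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed=None) -> PhyloTree:
    """Pure-birth tree: exponential waiting times, uniform lineage splits.

    Ultrametric by construction; tips are labelled S0001..S{n}. After the
    n-th lineage appears, the present is set one further exponential
    waiting time later.
    """
    if n_tips < 2:
        raise ValidationError(f"need >= 2 tips, got {n_tips}")
    if birth_rate <= 0:
        raise DomainError("birth_rate must be positive")
    rng = _rng(seed)
    root = Node(None, 0.0, [Node(None, 0.0), Node(None, 0.0)])
    active: List[Tuple[Node, float]] = [(c, 0.0) for c in root.children]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.length = t - born
        node.children = [Node(None, 0.0), Node(None, 0.0)]
        active.extend((c, t) for c in node.children)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, born in active:
        node.length = t - born
    counter = [0]

    def label(node: Node):  # left-to-right tip order for stable labels
        if node.is_leaf:
            counter[0] += 1
            node.label = f"S{counter[0]:04d}"
        for c in node.children:
            label(c)
    label(root)
    return PhyloTree(root)


# --------------------------------------------------------------------------
# traits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitModel:
    """Trait-evolution model: "bm", "lambda", or "ou" (stationary)."""

    kind: str = "bm"
    sigma2: float = 1.0
    lam: float = 1.0          # lambda models only
    alpha: float = 1.0        # OU models only
    theta: float = 0.0        # OU optimum / BM root value
    root: float = 0.0

    def __post_init__(self):
        if self.kind not in ("bm", "lambda", "ou"):
            raise ValidationError(f"unknown trait model {self.kind!r}")
        if self.sigma2 < 0:
            raise DomainError("sigma2 must be >= 0")


def trait_covariance(tree: PhyloTree, model: TraitModel
                     ) -> Tuple[List[str], np.ndarray]:
    if model.kind == "bm":
        labels, C = tree.shared_path_matrix()
        return labels, model.sigma2 * C
    if model.kind == "lambda":
        labels, V = lambda_covariance(tree, model.lam)
        return labels, model.sigma2 * V
    labels, M = ou_correlation(tree, model.alpha)
    return labels, model.sigma2 * M


def simulate_trait(tree: PhyloTree, model: TraitModel,
                   seed=None) -> Dict[str, float]:
    """One multivariate-normal draw under the trait model's covariance."""
    rng = _rng(seed)
    labels, V = trait_covariance(tree, model)
    mean = model.theta if model.kind == "ou" else model.root
    if model.sigma2 == 0:
        return {l: float(mean) for l in labels}
    jitter = 1e-12 * float(np.max(np.diag(V)))
    L = np.linalg.cholesky(V + jitter * np.eye(len(labels)))
    x = mean + L @ rng.standard_normal(len(labels))
    return dict(zip(labels, map(float, x)))


# --------------------------------------------------------------------------
# microsatellite study tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MsatSpec:
    n_loci: int = 30
    asymptote_log_mean: float = math.log(10.0)  # typical ~10-allele loci
    asymptote_log_sd: float = 0.4
    mu_true: float = 0.2
    ascertainment_delta: float = 0.1
    noise_sd: float = 0.1            # lognormal sd of count noise
    sample_size_range: Tuple[int, int] = (6, 200)
    scope: str = "regional"
    round_counts: bool = True

    def __post_init__(self):
        if self.noise_sd < 0 or self.asymptote_log_sd < 0:
            raise DomainError("noise SDs must be >= 0")
        if self.mu_true <= 0:
            raise DomainError("mu_true must be positive")


def _broken_stick(k: int, rng: np.random.Generator) -> np.ndarray:
    """Broken-stick allele frequency spectrum over k alleles."""
    cuts = np.sort(rng.uniform(size=k - 1))
    return np.diff(np.concatenate([[0.0], cuts, [1.0]]))


def simulate_msat_dataset(species: Union[PhyloTree, Sequence[str]],
                          spec: MsatSpec,
                          species_effects: Mapping[str, float],
                          seed=None,
                          mechanism: str = "model_faithful"
                          ) -> List[MicrosatRecord]:
    """Generate one locus x species microsatellite study table.

    ``model_faithful`` draws counts from the assumed saturating-curve
    model itself (with lognormal noise); ``gene_copy_sampling`` instead
    samples 2n gene copies from a broken-stick allele frequency spectrum
    and records the number of distinct alleles seen — a mechanistic
    check that the asymptotic-curve assumption is a fair description of
    allele discovery.  Each locus is ascertained on one randomly chosen
    source species.
    """
    if mechanism not in ("model_faithful", "gene_copy_sampling"):
        raise ValidationError(f"unknown mechanism {mechanism!r}")
    rng = _rng(seed)
    labels = species.tip_labels if isinstance(species, PhyloTree) else list(species)
    missing = [s for s in labels if s not in species_effects]
    if missing:
        raise ValidationError(f"species_effects missing for {missing}")
    lo, hi = spec.sample_size_range
    records: List[MicrosatRecord] = []
    for l in range(spec.n_loci):
        locus = f"L{l + 1:03d}"
        A = math.exp(rng.normal(spec.asymptote_log_mean, spec.asymptote_log_sd))
        source = labels[int(rng.integers(len(labels)))]
        for sp in labels:
            n = int(rng.integers(lo, hi + 1))
            asc = sp == source
            scale = math.exp(species_effects[sp]
                             + (spec.ascertainment_delta if asc else 0.0))
            if mechanism == "model_faithful":
                g = n * spec.mu_true / (1.0 + n * spec.mu_true)
                count = A * scale * g
                if spec.noise_sd > 0:
                    count *= math.exp(rng.normal(0.0, spec.noise_sd))
                if spec.round_counts:
                    count = max(1, round(count))
                else:
                    count = max(count, 1e-9)
            else:
                k = max(2, int(round(A * scale)))
                freqs = _broken_stick(k, rng)
                draws = rng.multinomial(2 * n, freqs)
                count = int(np.count_nonzero(draws))
                count = max(count, 1)
            records.append(MicrosatRecord(
                locus_id=locus, species_id=sp, study_id=f"sim_{locus}_{sp}",
                sample_size=n, n_alleles=count, ascertained=asc,
                scope=spec.scope))
    return records


# --------------------------------------------------------------------------
# mtDNA study tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MtdnaSpec:
    study_count_range: Tuple[int, int] = (1, 4)
    sample_size_range: Tuple[int, int] = (50, 400)
    study_noise_sd: float = 0.15     # lognormal sd around the species mean
    scope: str = "regional"


def simulate_mtdna_records(species_pi_means: Mapping[str, float],
                           spec: MtdnaSpec, seed=None) -> List[MtdnaRecord]:
    """Per species, a handful of studies with pi = mean x lognormal noise."""
    rng = _rng(seed)
    lo_s, hi_s = spec.study_count_range
    lo_n, hi_n = spec.sample_size_range
    records: List[MtdnaRecord] = []
    for sp in sorted(species_pi_means):
        mean = species_pi_means[sp]
        if mean < 0:
            raise ValidationError(f"negative pi mean for {sp}")
        for k in range(int(rng.integers(lo_s, hi_s + 1))):
            pi = mean * (math.exp(rng.normal(0.0, spec.study_noise_sd))
                         if spec.study_noise_sd > 0 else 1.0)
            records.append(MtdnaRecord(
                species_id=sp, study_id=f"sim_{sp}_{k + 1}",
                sample_size=int(rng.integers(lo_n, hi_n + 1)),
                pi_percent=pi, scope=spec.scope))
    return records


# --------------------------------------------------------------------------
# factor tables with planted effects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_species: int = 42
    birth_rate: float = 1.0
    msat: MsatSpec = field(default_factory=MsatSpec)
    mtdna: MtdnaSpec = field(default_factory=MtdnaSpec)
    matrilineal_fraction: float = 5.0 / 42.0
    matrilineal_pi_multiplier: float = 0.3
    # planted drivers
    pop_size_effect: float = 0.8     # slope of nuclear effect on z(log10 N)
    lat_range_pi_effect: float = 0.5  # slope of log pi mean on z(lat range)
    species_effect_noise_sd: float = 0.2
    pi_mean_base: float = 1.0        # percent
    pi_mean_noise_sd: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.matrilineal_fraction <= 1.0:
            raise DomainError("matrilineal_fraction must be in [0, 1]")
        if not 0.0 < self.matrilineal_pi_multiplier <= 1.0:
            raise DomainError("matrilineal_pi_multiplier must be in (0, 1]")


def _standardize(values: Dict[str, float]) -> Dict[str, float]:
    arr = np.array(list(values.values()))
    sd = arr.std()
    if sd == 0:
        return {k: 0.0 for k in values}
    mean = arr.mean()
    return {k: float((v - mean) / sd) for k, v in values.items()}


def _latent(tree: PhyloTree, rng: np.random.Generator) -> Dict[str, float]:
    """A standardized Brownian latent trait (unit marginal variance)."""
    return _standardize(simulate_trait(tree, TraitModel("bm", sigma2=1.0), rng))


def _threshold(latent: Mapping[str, float], levels: Sequence,
               probs: Sequence[float]) -> Dict[str, object]:
    """Map a latent trait to categorical levels by quantile thresholds."""
    species = sorted(latent, key=lambda s: latent[s])
    n = len(species)
    bounds = np.cumsum(probs)[:-1]
    out: Dict[str, object] = {}
    for i, sp in enumerate(species):
        q = (i + 0.5) / n
        out[sp] = levels[int(np.searchsorted(bounds, q))]
    return out


def simulate_factor_table(tree: PhyloTree, config: SimulationConfig,
                          seed=None
                          ) -> Tuple[Dict[str, SpeciesFactors], Dict]:
    """Factor table plus the ground truth that generated it.

    Continuous factors are Brownian traits rescaled to realistic ranges;
    categoricals threshold latent Brownian traits; missingness mimics the
    coverage of a literature compilation (population size ~83%, lifespan
    ~74%, ...).  Returns ``(factors, truth)`` where ``truth`` holds the
    planted per-species nuclear species effects, mitochondrial means, the
    matrilineal flags, and the latent drivers.
    """
    rng = _rng(seed if seed is not None else config.seed)
    labels = tree.tip_labels
    n = len(labels)

    z_pop = _latent(tree, rng)
    z_lat = _latent(tree, rng)
    z_len = _latent(tree, rng)
    z_life = _latent(tree, rng)
    z_eq = _latent(tree, rng)
    z_tax = _latent(tree, rng)
    z_fam = _latent(tree, rng)
    z_geo = _latent(tree, rng)
    z_hab = _latent(tree, rng)
    z_temp = _latent(tree, rng)
    z_grp = _latent(tree, rng)
    z_soc = _latent(tree, rng)

    n_myst = max(2, round(n * 11 / 42))
    suborder = _threshold(z_tax, ["Mysticete", "Odontocete"],
                          [n_myst / n, 1 - n_myst / n])
    myst_fams = ["Balaenidae", "Balaenopteridae", "Eschrichtiidae"]
    odon_fams = ["Delphinidae", "Monodontidae", "Ziphiidae", "Kogiidae",
                 "Phocoenidae", "Physeteridae", "Pontoporiidae"]
    family = {}
    for group, fams in ((
            [s for s in labels if suborder[s] == "Mysticete"], myst_fams), (
            [s for s in labels if suborder[s] == "Odontocete"], odon_fams)):
        sub = {s: z_fam[s] for s in group}
        family.update(_threshold(sub, fams, [1.0 / len(fams)] * len(fams)))

    whaling1 = _threshold(z_len, ["None", "Some", "Extensive"], [.4, .35, .25])
    hemisphere = _threshold(z_geo, ["Northern", "Southern"], [.6, .4])
    ocean1 = _threshold(z_geo, [1, 2, 3, 4, 5], [.25, .25, .2, .15, .15])
    ocean2 = _threshold(z_hab, ["Atlantic", "Pacific", "Both"], [.3, .3, .4])
    habitat = _threshold(z_hab, ["Neritic", "Oceanic", "Both"], [.3, .3, .4])
    temperature = _threshold(z_temp, ["TropicalTemperate", "Polar",
                                      "Cosmopolitan"], [.55, .2, .25])
    group_size = _threshold(z_grp, [1, 2, 3, 4], [.25, .3, .25, .2])
    trend = _threshold(z_pop, ["Decreasing", "Stable", "Increasing"],
                       [.35, .45, .2])
    iucn = _threshold({s: -z_pop[s] + 0.5 * rng.standard_normal()
                       for s in labels}, ["LC", "NT", "VU", "EN"],
                      [.5, .2, .15, .15])

    # matrilineal species: drawn among odontocetes (the real ones all are)
    odon = [s for s in labels if suborder[s] == "Odontocete"]
    k_mat = min(len(odon), round(config.matrilineal_fraction * n))
    mat_scores = sorted(odon, key=lambda s: z_soc[s])
    matrilineal = set(mat_scores[:k_mat])

    # planted ground truth
    species_effects = {
        s: config.pop_size_effect * z_pop[s]
        + float(rng.normal(0.0, config.species_effect_noise_sd))
        for s in labels}
    centre = float(np.mean(list(species_effects.values())))
    species_effects = {s: v - centre for s, v in species_effects.items()}
    pi_means = {
        s: config.pi_mean_base
        * math.exp(config.lat_range_pi_effect * z_lat[s]
                   + float(rng.normal(0.0, config.pi_mean_noise_sd)))
        * (config.matrilineal_pi_multiplier if s in matrilineal else 1.0)
        for s in labels}

    def miss(frac: float) -> set:
        k = round(frac * n)
        return set(rng.choice(labels, size=k, replace=False)) if k else set()

    missing_pop = miss(7 / 42)
    missing_lat = miss(2 / 42)
    missing_len = miss(4 / 42)
    missing_gen = miss(5 / 42)
    missing_life = miss(11 / 42)
    missing_iucn = miss(15 / 42)
    missing_trend = miss(31 / 42)

    factors: Dict[str, SpeciesFactors] = {}
    for s in labels:
        odont = suborder[s] == "Odontocete"
        factors[s] = SpeciesFactors(
            species_id=s,
            suborder=suborder[s],
            family=family[s],
            whaling1=whaling1[s],
            whaling2="Harvested" if whaling1[s] != "None" else "NotHarvested",
            hemisphere=hemisphere[s],
            ocean1=ocean1[s],
            ocean2=ocean2[s],
            habitat=habitat[s],
            temperature=temperature[s],
            group_size=group_size[s],
            social_structure=("Matrilineal" if s in matrilineal
                              else "NotMatrilineal"),
            population_size=(None if s in missing_pop
                             else 10.0 ** (5.0 + z_pop[s])),
            iucn_current=None if s in missing_iucn else iucn[s],
            iucn_1990s=None if s in missing_iucn else iucn[s],
            population_trend=None if s in missing_trend else trend[s],
            latitudinal_range=(None if s in missing_lat
                               else float(np.clip(60 + 25 * z_lat[s], 5, 150))),
            max_length=(None if s in missing_len
                        else float(np.clip(math.exp(2.0 + 0.8 * z_len[s]),
                                           1.2, 33.0))),
            generation_time=(None if s in missing_gen
                             else float(np.clip(15 + 8 * z_life[s], 5, 45))),
            lifespan=(None if s in missing_life
                      else float(np.clip(40 + 25 * z_life[s], 10, 211))),
            eq=(float(np.clip(2.0 + z_eq[s], 0.4, 5.0)) if odont else None),
            breeding_strategy=(None if odont else
                               ("Congregate" if z_grp[s] > 0 else "Disperse")),
        )

    truth = {
        "species_effects": species_effects,
        "pi_means": pi_means,
        "matrilineal": sorted(matrilineal),
        "latents": {"log10_population_size_z": z_pop,
                    "latitudinal_range_z": z_lat},
        "pop_size_effect": config.pop_size_effect,
        "lat_range_pi_effect": config.lat_range_pi_effect,
        "matrilineal_pi_multiplier": config.matrilineal_pi_multiplier,
    }
    return factors, truth


def simulate_study(config: SimulationConfig
                   ) -> Dict[str, object]:
    """Generate one full synthetic study bundle (both scopes).

    Returns a dict with the tree, factor table, ground truth, and the four
    study tables (msat/mtdna x regional/rangewide), all reproducible from
    ``config.seed`` alone.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_species, config.birth_rate, rng)
    factors, truth = simulate_factor_table(tree, config, rng)
    bundle: Dict[str, object] = {
        "tree": tree, "factors": factors, "truth": truth, "config": config}
    for scope in ("regional", "rangewide"):
        mspec = MsatSpec(**{**asdict(config.msat), "scope": scope})
        dspec = MtdnaSpec(**{**asdict(config.mtdna), "scope": scope})
        bundle[f"msat_{scope}"] = simulate_msat_dataset(
            tree, mspec, truth["species_effects"], rng)
        bundle[f"mtdna_{scope}"] = simulate_mtdna_records(
            truth["pi_means"], dspec, rng)
    return bundle
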