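"""Domain record types: study tables, species factors, diversity estimates.

The analysis operates on three tabular inputs — a microsatellite study table
(one row per locus x species x study), an mtDNA study table (published
control-region nucleotide diversities, pi in %), and a species factor table
with up to 21 candidate predictors of genetic diversity — plus a dated
phylogeny (see :mod:`cetadiv.tree`).

Every record validates its invariants on construction so that malformed
inputs fail early with a message naming the offending field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

from .errors import ValidationError

#: The two study-scope classes. A study is "rangewide" when its samples cover
#: at least 25% of the species range or an entire ocean basin, "regional"
#: otherwise.
SCOPES = ("regional", "rangewide")

#: Marker codes: mitochondrial pi (R = regional, O = rangewide/"overall") and
#: relative nuclear microsatellite diversity at the same two scales.
MARKERS = ("piR", "piO", "micR", "micO")

SCOPE_TO_PI_MARKER = {"regional": "piR", "rangewide": "piO"}
SCOPE_TO_MIC_MARKER = {"regional": "micR", "rangewide": "micO"}


def normalize_scope(value: str) -> str:
    s = str(value).strip().lower()
    if s not in SCOPES:
        raise ValidationError(f"scope must be one of {SCOPES}, got {value!r}")
    return s


@dataclass(frozen=True)
class MicrosatRecord:
    """One published use of one microsatellite locus on one species."""

    locus_id: str
    species_id: str
    study_id: str
    sample_size: int  # individuals genotyped
    n_alleles: int    # distinct alleles observed
    ascertained: bool  # locus originally developed on this species
    scope: str        # "regional" | "rangewide"

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValidationError(
                f"sample_size must be >= 1, got {self.sample_size} "
                f"(locus {self.locus_id}, species {self.species_id})")
        if self.n_alleles < 1:
            raise ValidationError(
                f"n_alleles must be >= 1, got {self.n_alleles} "
                f"(locus {self.locus_id}, species {self.species_id})")
        object.__setattr__(self, "scope", normalize_scope(self.scope))


@dataclass(frozen=True)
class MtdnaRecord:
    """One published mtDNA control-region nucleotide diversity estimate."""

    species_id: str
    study_id: str
    sample_size: int
    pi_percent: float  # nucleotide diversity, in percent
    scope: str

    def __post_init__(self):
        if self.sample_size < 1:
            raise ValidationError(
                f"sample_size must be >= 1, got {self.sample_size} "
                f"(species {self.species_id}, study {self.study_id})")
        if self.pi_percent < 0:
            raise ValidationError(
                f"pi_percent must be >= 0, got {self.pi_percent} "
                f"(species {self.species_id}, study {self.study_id})")
        object.__setattr__(self, "scope", normalize_scope(self.scope))


#: Admissible level sets for every categorical factor.
FACTOR_LEVELS = {
    "iucn_current": ("LC", "NT", "VU", "EN"),
    "iucn_1990s": ("LC", "NT", "VU", "EN"),
    "population_trend": ("Decreasing", "Stable", "Increasing"),
    "whaling1": ("None", "Some", "Extensive"),
    "whaling2": ("Harvested", "NotHarvested"),
    "suborder": ("Mysticete", "Odontocete"),
    "family": (
        "Balaenidae", "Balaenopteridae", "Delphinidae", "Monodontidae",
        "Eschrichtiidae", "Ziphiidae", "Kogiidae", "Phocoenidae",
        "Physeteridae", "Pontoporiidae",
    ),
    "hemisphere": ("Northern", "Southern"),
    "ocean1": (1, 2, 3, 4, 5),
    "ocean2": ("Atlantic", "Pacific", "Both"),
    "habitat": ("Neritic", "Oceanic", "Both"),
    "temperature": ("TropicalTemperate", "Polar", "Cosmopolitan"),
    "group_size": (1, 2, 3, 4),
    "breeding_strategy": ("Congregate", "Disperse"),
    "social_structure": ("Matrilineal", "NotMatrilineal"),
}

#: Quantitative factors (population size is analysed on a log10 scale).
CONTINUOUS_FACTORS = (
    "population_size", "latitudinal_range", "max_length",
    "generation_time", "lifespan", "eq",
)

#: All 21 candidate predictors, in reporting order.
ALL_FACTORS = (
    "population_size", "iucn_current", "iucn_1990s", "population_trend",
    "whaling1", "whaling2", "suborder", "family", "latitudinal_range",
    "hemisphere", "ocean1", "ocean2", "habitat", "temperature",
    "max_length", "generation_time", "lifespan", "eq", "group_size",
    "breeding_strategy", "social_structure",
)


@dataclass(frozen=True)
class SpeciesFactors:
    """The candidate predictors for one species.

    ``None`` means the factor could not be determined for the species.
    The encephalization quotient (eq) is defined for Odontocetes only, and
    breeding strategy for Mysticetes only.
    """

    species_id: str
    suborder: str
    family: str
    whaling1: str
    whaling2: str
    hemisphere: str
    ocean1: int
    ocean2: str
    habitat: str
    temperature: str
    group_size: int
    social_structure: str
    population_size: Optional[float] = None    # individuals, raw (log10 for analysis)
    iucn_current: Optional[str] = None
    iucn_1990s: Optional[str] = None
    population_trend: Optional[str] = None
    latitudinal_range: Optional[float] = None  # degrees of latitude spanned
    max_length: Optional[float] = None         # metres, female
    generation_time: Optional[float] = None    # years
    lifespan: Optional[float] = None           # years
    eq: Optional[float] = None                 # encephalization quotient
    breeding_strategy: Optional[str] = None

    def __post_init__(self):
        for name, levels in FACTOR_LEVELS.items():
            value = getattr(self, name)
            if value is None:
                continue
            if value not in levels:
                raise ValidationError(
                    f"{name}={value!r} not in admissible levels {levels} "
                    f"(species {self.species_id})")
        for name in ("population_size", "max_length", "generation_time",
                     "lifespan", "eq"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(
                    f"{name} must be positive, got {value} "
                    f"(species {self.species_id})")
        if self.latitudinal_range is not None and self.latitudinal_range < 0:
            raise ValidationError(
                f"latitudinal_range must be >= 0, got {self.latitudinal_range} "
                f"(species {self.species_id})")
        if self.suborder == "Mysticete" and self.eq is not None:
            raise ValidationError(
                f"eq is defined for Odontocetes only but is set for the "
                f"Mysticete {self.species_id}")
        if self.suborder == "Odontocete" and self.breeding_strategy is not None:
            raise ValidationError(
                f"breeding_strategy is defined for Mysticetes only but is set "
                f"for the Odontocete {self.species_id}")


FACTOR_COLUMNS = tuple(
    f.name for f in fields(SpeciesFactors))  # species_id first


@dataclass(frozen=True)
class DiversityEstimate:
    """One per-species diversity value for one marker.

    Mitochondrial markers (piR, piO) carry pi in percent, so values are
    non-negative.  Microsatellite markers (micR, micO) carry the species
    effect of the mixed model, a log-scale relative allelic diversity
    centred on the cetacean average: a value below zero means lower than
    expected relative nuclear diversity.
    """

    species_id: str
    marker: str
    value: float
    n_studies_or_loci: int

    def __post_init__(self):
        if self.marker not in MARKERS:
            raise ValidationError(
                f"marker must be one of {MARKERS}, got {self.marker!r}")
        if self.marker in ("piR", "piO") and self.value < 0:
            raise ValidationError(
                f"{self.marker} value must be >= 0, got {self.value} "
                f"(species {self.species_id})")
        if self.n_studies_or_loci < 0:
            raise ValidationError("n_studies_or_loci must be >= 0")
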