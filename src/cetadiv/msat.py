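"""Relative nuclear diversity from microsatellite study tables.

Observed allele counts depend heavily on the number of individuals
genotyped, on the locus itself, and on whether the locus was developed
("ascertained") on the focal species.  The estimation chain is:

1. **Filtering** — keep records with at least two alleles and more than
   five individuals; then keep loci used on at least five species, and
   species typed at four or more of the retained loci.
2. **Sample-size correction** — allele discovery is modelled as a
   saturating curve ``a(n) = A_l * (n*mu) / (1 + n*mu)`` with a single
   per-individual discovery rate ``mu`` shared across loci and per-locus
   asymptotes ``A_l``.  Inverting the curve gives the printed correction
   ``corrected = observed * (1 + n*mu) / (n*mu)``.
3. **Mixed model** — ``log(corrected) ~ species (fixed, no intercept)
   + locus (random) + ascertained (fixed binary)``, fitted by REML.
   The centred species effects are the relative nuclear diversity
   estimates: below zero means less diverse than the cetacean average.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (ConvergenceError, DomainError, IdentifiabilityError,
                     ValidationError)
from .records import SCOPE_TO_MIC_MARKER, DiversityEstimate, MicrosatRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionModel", "MixedModelFit", "filter_msat_records", "fit_mu",
    "correct_allele_count", "fit_species_effects", "estimate_relative_diversity",
]


@dataclass
class CorrectionModel:
    """Fitted allele-discovery curve for one scope."""

    mu: float                       # per-individual discovery rate
    scope: str
    locus_asymptotes: Dict[str, float]  # locus_id -> saturation count A_l
    converged: bool
    rss: float
    n_records: int
    loss: str = "count"             # "count" | "log"


@dataclass
class MixedModelFit:
    """Species / locus / ascertainment decomposition of log corrected counts."""

    species_effects: Dict[str, float]  # centred: mean zero across species
    ascertainment_effect: float
    ascertainment_se: float
    locus_variance: float
    residual_variance: float
    log_likelihood: float
    n_records: int
    converged: bool = True
    n_loci_per_species: Dict[str, int] = field(default_factory=dict)


def filter_msat_records(records: Sequence[MicrosatRecord]
                        ) -> List[MicrosatRecord]:
    """Apply the inclusion filters, in one pass.

    Record level first (n_alleles >= 2 and sample_size > 5), then loci used
    on at least five distinct species, then species with at least four
    distinct retained loci.
    """
    if not records:
        return []
    scopes = {r.scope for r in records}
    if len(scopes) > 1:
        raise ValidationError(
            f"records mix scopes {sorted(scopes)}; filter one scope at a time")
    stage1 = [r for r in records if r.n_alleles >= 2 and r.sample_size > 5]

    species_per_locus: Dict[str, set] = {}
    for r in stage1:
        species_per_locus.setdefault(r.locus_id, set()).add(r.species_id)
    good_loci = {l for l, spp in species_per_locus.items() if len(spp) >= 5}
    stage2 = [r for r in stage1 if r.locus_id in good_loci]

    loci_per_species: Dict[str, set] = {}
    for r in stage2:
        loci_per_species.setdefault(r.species_id, set()).add(r.locus_id)
    good_species = {s for s, loci in loci_per_species.items() if len(loci) >= 4}
    return [r for r in stage2 if r.species_id in good_species]


def _saturation(n: np.ndarray, mu: float) -> np.ndarray:
    x = n * mu
    return x / (1.0 + x)


def _profile_asymptotes(records: Sequence[MicrosatRecord], mu: float,
                        loss: str) -> Tuple[Dict[str, float], float]:
    """For fixed mu, solve each locus asymptote in closed form; return RSS."""
    by_locus: Dict[str, List[MicrosatRecord]] = {}
    for r in records:
        by_locus.setdefault(r.locus_id, []).append(r)
    asym: Dict[str, float] = {}
    rss = 0.0
    for locus, recs in by_locus.items():
        y = np.array([r.n_alleles for r in recs], dtype=float)
        g = _saturation(np.array([r.sample_size for r in recs], dtype=float), mu)
        if loss == "count":
            a = float(np.dot(y, g) / np.dot(g, g))
            rss += float(np.sum((y - a * g) ** 2))
        else:  # multiplicative (lognormal) noise: least squares on log scale
            la = float(np.mean(np.log(y) - np.log(g)))
            a = math.exp(la)
            rss += float(np.sum((np.log(y) - la - np.log(g)) ** 2))
        asym[locus] = a
    return asym, rss


def fit_mu(records: Sequence[MicrosatRecord], scope: Optional[str] = None,
           loss: str = "count",
           bounds: Tuple[float, float] = (1e-4, 1e2)) -> CorrectionModel:
    """Fit the shared discovery rate ``mu`` and per-locus asymptotes.

    The per-locus asymptotes are profiled out in closed form, leaving a
    one-dimensional least-squares problem in ``log mu`` solved by bounded
    scalar minimisation.
    """
    records = list(records)
    if not records:
        raise ValidationError("no records to fit")
    if scope is None:
        scope = records[0].scope
    if len({r.sample_size for r in records}) < 2:
        raise IdentifiabilityError(
            "mu is not identifiable from a single distinct sample size")
    if loss not in ("count", "log"):
        raise ValueError(f"unknown loss {loss!r}")

    def objective(log_mu: float) -> float:
        return _profile_asymptotes(records, math.exp(log_mu), loss)[1]

    res = optimize.minimize_scalar(
        objective, bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded", options={"xatol": 1e-10})
    mu = float(math.exp(res.x))
    asym, rss = _profile_asymptotes(records, mu, loss)
    model = CorrectionModel(mu=mu, scope=scope, locus_asymptotes=asym,
                            converged=bool(res.success), rss=rss,
                            n_records=len(records), loss=loss)
    if not res.success:
        raise ConvergenceError("mu fit did not converge", best=model)
    return model


def correct_allele_count(n_alleles: float, sample_size: float,
                         mu: float) -> float:
    """Extrapolate an observed allele count to its saturation value.

    ``corrected = observed * (1 + n*mu) / (n*mu)``; always at least the
    observed count, and decreasing in sample size (small samples are
    corrected upwards more).
    """
    if mu <= 0:
        raise DomainError(f"mu must be positive, got {mu}")
    if n_alleles <= 0 or sample_size <= 0:
        raise DomainError("n_alleles and sample_size must be positive")
    x = sample_size * mu
    return n_alleles * (1.0 + x) / x


def _corrected_frame(records: Sequence[MicrosatRecord],
                     correction: CorrectionModel) -> pd.DataFrame:
    return pd.DataFrame({
        "log_corrected": [
            math.log(correct_allele_count(r.n_alleles, r.sample_size,
                                          correction.mu)) for r in records],
        "species_id": [r.species_id for r in records],
        "locus_id": [r.locus_id for r in records],
        "ascertained": [1.0 if r.ascertained else 0.0 for r in records],
    })


def fit_species_effects(records: Sequence[MicrosatRecord],
                        correction: CorrectionModel,
                        reml: bool = True) -> MixedModelFit:
    """REML fit of the species/locus/ascertainment mixed model.

    Species enter as fixed effects with no global intercept; loci as
    Gaussian random intercepts; ascertainment as a binary fixed covariate.
    Species effects are re-centred to mean zero for reporting, so the sign
    is directly interpretable (negative = below the cetacean average).
    """
    records = list(records)
    species = sorted({r.species_id for r in records})
    loci = sorted({r.locus_id for r in records})
    if len(species) < 2:
        raise IdentifiabilityError(
            f"need >= 2 species to identify relative diversity, got {species}")
    if len(loci) < 2:
        raise IdentifiabilityError("need >= 2 loci for a locus random effect")

    # species whose loci are entirely private cannot be compared reliably
    locus_species: Dict[str, set] = {}
    for r in records:
        locus_species.setdefault(r.locus_id, set()).add(r.species_id)
    for sp in species:
        own = {r.locus_id for r in records if r.species_id == sp}
        if all(locus_species[l] == {sp} for l in own):
            logger.warning("species %s shares no locus with any other species; "
                           "its effect is weakly identified", sp)

    df = _corrected_frame(records, correction)
    n_loci_per_species = df.groupby("species_id")["locus_id"].nunique().to_dict()

    # exact-fit fast path: REML breaks down when the residual variance is ~0
    X_fix = np.column_stack(
        [(df["species_id"] == sp).to_numpy(float) for sp in species]
        + [df["ascertained"].to_numpy(float)])
    y = df["log_corrected"].to_numpy(float)
    beta, rss_arr, *_ = np.linalg.lstsq(X_fix, y, rcond=None)
    resid = y - X_fix @ beta
    rss = float(resid @ resid)
    if rss / len(y) < 1e-12:
        eff = dict(zip(species, beta[:-1]))
        centre = float(np.mean(list(eff.values())))
        return MixedModelFit(
            species_effects={s: float(v - centre) for s, v in eff.items()},
            ascertainment_effect=float(beta[-1]), ascertainment_se=0.0,
            locus_variance=0.0, residual_variance=0.0,
            log_likelihood=math.inf, n_records=len(records), converged=True,
            n_loci_per_species=n_loci_per_species)

    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm("log_corrected ~ 0 + C(species_id) + ascertained",
                            df, groups=df["locus_id"])
        fit = model.fit(reml=reml, method=["lbfgs", "powell"])

    params = fit.params
    eff = {}
    for sp in species:
        eff[sp] = float(params[f"C(species_id)[{sp}]"])
    centre = float(np.mean(list(eff.values())))
    return MixedModelFit(
        species_effects={s: v - centre for s, v in eff.items()},
        ascertainment_effect=float(params["ascertained"]),
        ascertainment_se=float(fit.bse["ascertained"]),
        locus_variance=float(fit.cov_re.iloc[0, 0]),
        residual_variance=float(fit.scale),
        log_likelihood=float(fit.llf),
        n_records=len(records),
        converged=bool(fit.converged),
        n_loci_per_species=n_loci_per_species)


def estimate_relative_diversity(records: Sequence[MicrosatRecord],
                                scope: Optional[str] = None,
                                loss: str = "count",
                                return_fits: bool = False):
    """Full chain: filter -> fit mu -> correct -> mixed model -> estimates.

    Returns one :class:`DiversityEstimate` per retained species (marker
    micR for regional records, micO for rangewide); with
    ``return_fits=True`` also returns the correction and mixed-model fits.
    """
    records = list(records)
    if scope is None and records:
        scope = records[0].scope
    kept = filter_msat_records(records)
    if not kept:
        return ([], None, None) if return_fits else []
    correction = fit_mu(kept, scope=scope, loss=loss)
    mixed = fit_species_effects(kept, correction)
    marker = SCOPE_TO_MIC_MARKER[scope]
    estimates = [
        DiversityEstimate(species_id=sp, marker=marker, value=val,
                          n_studies_or_loci=mixed.n_loci_per_species.get(sp, 0))
        for sp, val in sorted(mixed.species_effects.items())]
    if return_fits:
        return estimates, correction, mixed
    return estimates
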