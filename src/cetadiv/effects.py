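"""Univariate factor screening with effect sizes.

Categorical factors are tested with one-way ANOVA; effect size is Cohen's
d for two-level factors and omega-squared otherwise.  Continuous factors
are tested with phylogenetic independent contrasts (plain Pearson
correlation available as a diagnostic).  An effect is called strong at
the conventional thresholds d > 0.8, omega^2 > 0.14, |r| > 0.4 (strict
inequalities).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .comparative import pic_correlation
from .design import factor_frame
from .errors import DegenerateModelError, ValidationError
from .records import (ALL_FACTORS, DiversityEstimate, SpeciesFactors)
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult", "EffectResult", "oneway_anova", "cohens_d",
    "omega_squared", "pearson_r", "classify_effect", "screen_all",
    "STRONG_THRESHOLDS",
]

STRONG_THRESHOLDS = {"cohens_d": 0.8, "omega_squared": 0.14, "pearson_r": 0.4}


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ssb: float  # between-group sum of squares
    ssw: float  # within-group sum of squares
    sst: float
    ms_within: float


def oneway_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way ANOVA with the full sums-of-squares decomposition."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValidationError("values and groups must be parallel")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValidationError(f"need >= 2 groups, got {len(labels)}")
    grand = values.mean()
    ssb = ssw = 0.0
    for g in labels:
        v = values[groups == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += float(np.sum((v - v.mean()) ** 2))
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    if df2 < 1:
        raise ValidationError("no within-group degrees of freedom")
    msb = ssb / df1
    msw = ssw / df2
    if msw == 0.0:
        F = math.inf if msb > 0 else 0.0
        p = 0.0 if msb > 0 else 1.0
    else:
        F = msb / msw
        p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(F=F, df1=df1, df2=df2, p=p, ssb=ssb, ssw=ssw,
                       sst=ssb + ssw, ms_within=msw)


def cohens_d(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Unsigned standardized mean difference with df-weighted pooled SD."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each group needs >= 2 values for Cohen's d")
    n1, n2 = len(g1), len(g2)
    pooled_var = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) \
        / (n1 + n2 - 2)
    if pooled_var == 0.0:
        if g1.mean() == g2.mean():
            return 0.0
        raise DegenerateModelError("zero pooled SD with unequal means")
    return abs(g1.mean() - g2.mean()) / math.sqrt(pooled_var)


def omega_squared(anova: AnovaResult) -> float:
    """Small-sample-corrected share of variance: (SSB - df1*MSW)/(SST + MSW).

    May be negative when F < 1; reported as computed, not clamped.
    """
    denom = anova.sst + anova.ms_within
    if denom == 0.0:
        return 0.0
    return (anova.ssb - anova.df1 * anova.ms_within) / denom


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Product-moment correlation and its two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need equal-length sequences of >= 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def classify_effect(kind: str, value: float) -> bool:
    """Strict-threshold call of a strong effect (r by absolute value)."""
    if kind not in STRONG_THRESHOLDS:
        raise ValidationError(f"unknown effect kind {kind!r}")
    v = abs(value) if kind == "pearson_r" else value
    return v > STRONG_THRESHOLDS[kind]


@dataclass
class EffectResult:
    """One factor x marker screening row (Tables-2/3-style long format)."""

    factor: str
    marker: str
    n: int
    statistic_kind: str  # "F" (ANOVA or PIC regression) — r lives in effect
    statistic: float
    p: float
    effect_kind: str     # "cohens_d" | "omega_squared" | "pearson_r"
    effect_value: float
    strong: bool


def _estimate_map(estimates: Sequence[DiversityEstimate]
                  ) -> Dict[str, Dict[str, float]]:
    out: Dict[str, Dict[str, float]] = {}
    for e in estimates:
        out.setdefault(e.marker, {})[e.species_id] = e.value
    return out


def screen_all(factors: Mapping[str, SpeciesFactors],
               estimates: Sequence[DiversityEstimate],
               tree: Optional[PhyloTree] = None,
               continuous_method: str = "pic",
               exclude_matrilineal: bool = False,
               min_cases: int = 5,
               ocean1_as_continuous: bool = False,
               factor_list: Optional[Sequence[str]] = None
               ) -> List[EffectResult]:
    """Screen every factor against every marker present in ``estimates``.

    Continuous factors use PIC correlations on the tree pruned to the
    complete cases (``continuous_method="pearson"`` falls back to plain
    correlation, for diagnostics or when no tree is available).  With
    ``exclude_matrilineal`` the matrilineal species are dropped before
    screening, the variant used to expose effects that their depressed
    mitochondrial diversity masks.  Factor x marker pairs that cannot be
    tested are logged with the reason and omitted.
    """
    frame = factor_frame(factors)  # population size already log10
    if exclude_matrilineal:
        frame = frame[frame["social_structure"] != "Matrilineal"]
    by_marker = _estimate_map(estimates)
    factor_list = list(factor_list) if factor_list is not None else \
        [f for f in ALL_FACTORS]
    results: List[EffectResult] = []

    for marker, value_map in sorted(by_marker.items()):
        vals = pd.Series(value_map, dtype=float)
        vals = vals[vals.index.isin(frame.index)]
        for factor in factor_list:
            fac = frame[factor].reindex(vals.index).dropna()
            common = fac.index.intersection(vals.index)
            y = vals.loc[common]
            f = fac.loc[common]
            n = len(common)
            if n < min_cases:
                logger.info("skip %s x %s: only %d complete cases",
                            factor, marker, n)
                continue
            continuous = factor in ("population_size", "latitudinal_range",
                                    "max_length", "generation_time",
                                    "lifespan", "eq") or \
                (factor == "ocean1" and ocean1_as_continuous)
            if continuous:
                if continuous_method == "pic":
                    if tree is None:
                        logger.info("skip %s x %s: no tree for PICs",
                                    factor, marker)
                        continue
                    keep = [s for s in common if s in set(tree.tip_labels)]
                    if len(keep) < max(min_cases, 4):
                        logger.info("skip %s x %s: only %d species in tree",
                                    factor, marker, len(keep))
                        continue
                    sub = tree.prune(keep)
                    r, F, p = pic_correlation(
                        sub, f.loc[keep].astype(float).to_dict(),
                        y.loc[keep].to_dict())
                    n = len(keep)
                else:
                    r, p = pearson_r(f.astype(float), y)
                    df2 = n - 2
                    F = r * r * df2 / (1 - r * r) if abs(r) < 1 else math.inf
                results.append(EffectResult(
                    factor=factor, marker=marker, n=n, statistic_kind="F",
                    statistic=F, p=p, effect_kind="pearson_r", effect_value=r,
                    strong=classify_effect("pearson_r", r)))
            else:
                levels = pd.unique(f)
                if len(levels) < 2:
                    logger.info("skip %s x %s: single level", factor, marker)
                    continue
                counts = f.value_counts()
                if len(y) - len(levels) < 1:
                    logger.info("skip %s x %s: no residual df", factor, marker)
                    continue
                an = oneway_anova(y.to_numpy(), f.to_numpy())
                if len(levels) == 2:
                    if counts.min() < 2:
                        logger.info("skip %s x %s: a level has < 2 cases",
                                    factor, marker)
                        continue
                    g1 = y[f == levels[0]].to_numpy()
                    g2 = y[f == levels[1]].to_numpy()
                    kind, eff = "cohens_d", cohens_d(g1, g2)
                else:
                    kind, eff = "omega_squared", omega_squared(an)
                results.append(EffectResult(
                    factor=factor, marker=marker, n=n, statistic_kind="F",
                    statistic=an.F, p=an.p, effect_kind=kind, effect_value=eff,
                    strong=classify_effect(kind, eff)))
    return results


def effects_frame(results: Sequence[EffectResult]) -> pd.DataFrame:
    """Long-format screening table (factor, marker, n, F, p, effect, strong)."""
    return pd.DataFrame([{
        "factor": r.factor, "marker": r.marker, "n": r.n,
        "statistic_kind": r.statistic_kind, "statistic": r.statistic,
        "p": r.p, "effect_kind": r.effect_kind,
        "effect_value": r.effect_value, "strong": r.strong}
        for r in results])
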