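"""Ordinary linear models, AIC, and bidirectional stepwise selection.

AIC uses the full Gaussian log-likelihood (2*pi constant included) and
counts the error variance among the parameters, matching the values
standard statistical software prints for ``lm`` fits.  The stepwise
search starts from the null model, considers every single-term addition
and deletion at each step, and applies the best strictly-AIC-decreasing
move; simpler models within ~5 AIC units of the best are preferred by the
parsimony rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import build_design, check_full_rank, complete_cases
from .errors import (DegenerateModelError, RankDeficiencyError,
                     ValidationError)

logger = logging.getLogger(__name__)

__all__ = ["LinearModelFit", "StepwiseResult", "fit_linear_model",
           "stepwise_aic", "parsimony_select", "gaussian_aic"]


def gaussian_aic(rss: float, n: int, k_params: int) -> Tuple[float, float]:
    """(AIC, log-likelihood) for a Gaussian model with ML variance rss/n."""
    if rss <= 0:
        raise DegenerateModelError(
            "zero residual sum of squares: the Gaussian log-likelihood "
            "is unbounded")
    ll = -0.5 * n * (math.log(2 * math.pi) + math.log(rss / n) + 1.0)
    return 2.0 * k_params - 2.0 * ll, ll


@dataclass
class LinearModelFit:
    terms: Tuple[str, ...]
    coefficients: Dict[str, float]
    rss: float
    n: int
    k_params: int          # regression coefficients + error variance
    aic: float
    log_likelihood: float

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass
class StepwiseResult:
    path: List[Tuple[str, Optional[str], float]]  # (action, term, aic)
    selected: LinearModelFit
    candidate_pool: Tuple[str, ...]
    species_set: Tuple[str, ...]


def fit_linear_model(response: pd.Series, terms: Sequence[str],
                     data: pd.DataFrame,
                     ocean1_as_continuous: bool = False) -> LinearModelFit:
    """Least-squares fit with dummy-coded categorical terms and full-Gaussian AIC."""
    idx = complete_cases(data, terms, response)
    sub = data.loc[idx]
    y = response.loc[idx].to_numpy(dtype=float)
    n = len(y)
    X, names, _ = build_design(sub, terms, intercept=True,
                               ocean1_as_continuous=ocean1_as_continuous)
    if n < X.shape[1] + 2:
        raise ValidationError(
            f"{n} complete cases cannot support {X.shape[1]} parameters")
    check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    k = X.shape[1] + 1  # + error variance
    aic, ll = gaussian_aic(rss, n, k)
    return LinearModelFit(terms=tuple(terms),
                          coefficients=dict(zip(names, map(float, beta))),
                          rss=rss, n=n, k_params=k, aic=aic,
                          log_likelihood=ll)


def stepwise_aic(response: pd.Series, candidate_terms: Sequence[str],
                 data: pd.DataFrame, start: str = "null",
                 ocean1_as_continuous: bool = False) -> StepwiseResult:
    """Bidirectional stepwise AIC search over a candidate term pool.

    The species set is frozen to the complete cases over the response and
    the whole candidate pool before searching, so every AIC along the
    path is computed on the same data.  Ties between equally good moves
    are broken by preferring deletions, then lexicographic term order.
    """
    pool = tuple(candidate_terms)
    idx = complete_cases(data, pool, response)
    sub = data.loc[idx]
    resp = response.loc[idx]
    if len(idx) == 0:
        raise ValidationError("no complete cases over the candidate pool")

    def fit(terms: Sequence[str]) -> Optional[LinearModelFit]:
        try:
            return fit_linear_model(resp, terms, sub,
                                    ocean1_as_continuous=ocean1_as_continuous)
        except (ValidationError, DegenerateModelError,
                RankDeficiencyError) as exc:
            logger.debug("skip terms %s: %s", terms, exc)
            return None

    if not pool:
        null = fit(())
        logger.info("empty candidate pool; returning the null model")
        return StepwiseResult(path=[("stop", None, null.aic)], selected=null,
                              candidate_pool=pool,
                              species_set=tuple(idx))

    current_terms: List[str] = [] if start == "null" else list(pool)
    current = fit(current_terms)
    if current is None:
        raise ValidationError("the starting model could not be fitted")
    path: List[Tuple[str, Optional[str], float]] = [
        ("start", None, current.aic)]

    while True:
        moves: List[Tuple[float, int, str, str, LinearModelFit]] = []
        # deletions first (preferred on ties via the sort key below)
        for term in current_terms:
            trial = [t for t in current_terms if t != term]
            m = fit(trial)
            if m is not None:
                moves.append((m.aic, 0, term, "drop", m))
        for term in pool:
            if term in current_terms:
                continue
            m = fit(current_terms + [term])
            if m is not None:
                moves.append((m.aic, 1, term, "add", m))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1], t[2]))
        best_aic, _, best_term, action, best_fit = moves[0]
        if best_aic >= current.aic - 1e-10:
            break
        if action == "drop":
            current_terms.remove(best_term)
        else:
            current_terms.append(best_term)
        current = best_fit
        path.append((action, best_term, best_aic))

    path.append(("stop", None, current.aic))
    return StepwiseResult(path=path, selected=current, candidate_pool=pool,
                          species_set=tuple(idx))


def parsimony_select(models: Sequence[LinearModelFit],
                     delta: float = 5.0) -> LinearModelFit:
    """Among models within ``delta`` AIC of the best, take the simplest.

    Ties on term count are broken by lower AIC.
    """
    models = list(models)
    if not models:
        raise ValidationError("no models to select from")
    best_aic = min(m.aic for m in models)
    near = [m for m in models if m.aic - best_aic < delta]
    return min(near, key=lambda m: (m.n_terms, m.aic))
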