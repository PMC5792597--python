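"""Design-matrix construction shared by the linear models and PGLS.

Terms are factor names, taken in the order given (tests of the fitted
models are sequential in this order).  Categorical factors are
dummy-coded against the first level in sorted order; quantitative
factors enter as single columns.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import RankDeficiencyError
from .records import (ALL_FACTORS, CONTINUOUS_FACTORS, FACTOR_COLUMNS,
                      SpeciesFactors)


def factor_frame(factors: Mapping[str, SpeciesFactors],
                 log10_population: bool = True) -> pd.DataFrame:
    """Tabulate species factors for analysis, indexed by species_id.

    Population size is log10-transformed (its analysis scale); ocean1 and
    group_size are kept as integers and treated as categorical by default
    downstream.
    """
    rows = {}
    for sid, f in factors.items():
        row = {name: getattr(f, name) for name in FACTOR_COLUMNS
               if name != "species_id"}
        if log10_population and row["population_size"] is not None:
            row["population_size"] = math.log10(row["population_size"])
        rows[sid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "species_id"
    return df.sort_index()


def is_continuous(term: str, values: pd.Series,
                  ocean1_as_continuous: bool = False) -> bool:
    if term == "ocean1":
        return ocean1_as_continuous
    if term in CONTINUOUS_FACTORS:
        return True
    if term in ALL_FACTORS:
        return False
    # unknown column: decide from dtype
    return pd.api.types.is_numeric_dtype(values.dropna().infer_objects())


def build_design(data: pd.DataFrame, terms: Sequence[str],
                 intercept: bool = True,
                 ocean1_as_continuous: bool = False
                 ) -> Tuple[np.ndarray, List[str], Dict[str, List[int]]]:
    """Build (X, column_names, term -> column indices).

    ``data`` must already be restricted to complete cases over ``terms``.
    The intercept occupies column 0 under term name "Intercept".
    """
    cols: List[np.ndarray] = []
    names: List[str] = []
    term_cols: Dict[str, List[int]] = {}
    if intercept:
        cols.append(np.ones(len(data)))
        names.append("Intercept")
        term_cols["Intercept"] = [0]
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"term {term!r} not in data columns")
        series = data[term]
        if series.isna().any():
            raise ValueError(f"term {term!r} has missing values; restrict to "
                             f"complete cases before building the design")
        start = len(cols)
        if is_continuous(term, series, ocean1_as_continuous):
            cols.append(series.astype(float).to_numpy())
            names.append(term)
        else:
            levels = sorted(series.unique(), key=str)
            for level in levels[1:]:  # first level is the reference
                cols.append((series == level).astype(float).to_numpy())
                names.append(f"{term}[{level}]")
        term_cols[term] = list(range(start, len(cols)))
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return X, names, term_cols


def check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise :class:`RankDeficiencyError` naming aliased columns."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    aliased = []
    kept: List[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) > len(kept):
            kept.append(j)
        else:
            aliased.append(names[j])
    raise RankDeficiencyError(
        f"design matrix is rank deficient; aliased columns: {aliased}",
        aliased=aliased)


def complete_cases(data: pd.DataFrame, terms: Sequence[str],
                   response: Optional[pd.Series] = None) -> pd.Index:
    """Index of rows with no missing value in ``terms`` (and the response)."""
    mask = pd.Series(True, index=data.index)
    for term in terms:
        mask &= data[term].notna()
    if response is not None:
        resp = response.reindex(data.index)
        mask &= resp.notna()
    return data.index[mask]
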