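"""Delimited-table input/output for the three study tables.

Files are comma-separated UTF-8 with a header row (tab-separated accepted
via ``sep="\\t"``).  Empty cells mean "missing".  Validation errors name the
1-based data row so a curator can find the offending line.  Species
identifiers are matched after trimming whitespace; matching is
case-insensitive with an optional synonym map.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError
from .records import (
    FACTOR_COLUMNS,
    DiversityEstimate,
    MicrosatRecord,
    MtdnaRecord,
    SpeciesFactors,
)

MSAT_COLUMNS = ("locus_id", "species_id", "study_id", "sample_size",
                "n_alleles", "ascertained", "scope")
MTDNA_COLUMNS = ("species_id", "study_id", "sample_size", "pi_percent", "scope")

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def _cell(row, name) -> Optional[str]:
    v = row[name]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def _parse_int(s: str, name: str, rownum: int):
    try:
        return int(float(s))
    except (TypeError, ValueError):
        raise ValidationError(f"row {rownum}: {name}={s!r} is not an integer")


def _parse_float(s: str, name: str, rownum: int):
    try:
        return float(s)
    except (TypeError, ValueError):
        raise ValidationError(f"row {rownum}: {name}={s!r} is not a number")


def _parse_bool(s: str, name: str, rownum: int) -> bool:
    low = str(s).strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValidationError(f"row {rownum}: {name}={s!r} is not a boolean")


def read_msat_table(path, sep: str = ",") -> List[MicrosatRecord]:
    """Read a microsatellite study table (one row per locus x species x study)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, MSAT_COLUMNS, path)
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(MicrosatRecord(
                locus_id=_cell(row, "locus_id"),
                species_id=_cell(row, "species_id"),
                study_id=_cell(row, "study_id"),
                sample_size=_parse_int(_cell(row, "sample_size"), "sample_size", i),
                n_alleles=_parse_int(_cell(row, "n_alleles"), "n_alleles", i),
                ascertained=_parse_bool(_cell(row, "ascertained"), "ascertained", i),
                scope=_cell(row, "scope"),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_msat_table(records: Sequence[MicrosatRecord], path, sep: str = ",") -> None:
    df = pd.DataFrame([{
        "locus_id": r.locus_id, "species_id": r.species_id,
        "study_id": r.study_id, "sample_size": r.sample_size,
        "n_alleles": r.n_alleles, "ascertained": r.ascertained,
        "scope": r.scope} for r in records], columns=list(MSAT_COLUMNS))
    df.to_csv(path, sep=sep, index=False)


def read_mtdna_table(path, sep: str = ",") -> List[MtdnaRecord]:
    """Read an mtDNA study table of published control-region pi values (%)."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, MTDNA_COLUMNS, path)
    records = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(MtdnaRecord(
                species_id=_cell(row, "species_id"),
                study_id=_cell(row, "study_id"),
                sample_size=_parse_int(_cell(row, "sample_size"), "sample_size", i),
                pi_percent=_parse_float(_cell(row, "pi_percent"), "pi_percent", i),
                scope=_cell(row, "scope"),
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def write_mtdna_table(records: Sequence[MtdnaRecord], path, sep: str = ",") -> None:
    df = pd.DataFrame([{
        "species_id": r.species_id, "study_id": r.study_id,
        "sample_size": r.sample_size, "pi_percent": r.pi_percent,
        "scope": r.scope} for r in records], columns=list(MTDNA_COLUMNS))
    df.to_csv(path, sep=sep, index=False)


_INT_FACTORS = ("ocean1", "group_size")
_FLOAT_FACTORS = ("population_size", "latitudinal_range", "max_length",
                  "generation_time", "lifespan", "eq")


def read_factors_table(path, sep: str = ",",
                       synonyms: Optional[Mapping[str, str]] = None
                       ) -> Dict[str, SpeciesFactors]:
    """Read the species factor table into ``{species_id: SpeciesFactors}``.

    Categorical cells are validated against the admissible level sets;
    empty cells mean the factor is unknown for that species.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=[""])
    _require_columns(df, FACTOR_COLUMNS, path)
    synonyms = {k.strip().lower(): v for k, v in (synonyms or {}).items()}
    out: Dict[str, SpeciesFactors] = {}
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        kwargs = {}
        for name in FACTOR_COLUMNS:
            raw = _cell(row, name)
            if name == "species_id":
                sid = raw
                if sid is None:
                    raise ValidationError(f"{path}: row {i}: empty species_id")
                sid = synonyms.get(sid.lower(), sid)
                kwargs[name] = sid
            elif raw is None:
                kwargs[name] = None
            elif name in _INT_FACTORS:
                kwargs[name] = _parse_int(raw, name, i)
            elif name in _FLOAT_FACTORS:
                kwargs[name] = _parse_float(raw, name, i)
            else:
                kwargs[name] = raw
        try:
            rec = SpeciesFactors(**kwargs)
        except (ValidationError, TypeError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
        key = rec.species_id.strip().lower()
        if key in out:
            raise ValidationError(
                f"{path}: row {i}: duplicate species {rec.species_id!r}")
        out[rec.species_id] = rec
    return out


def write_factors_table(factors: Mapping[str, SpeciesFactors], path,
                        sep: str = ",") -> None:
    rows = []
    for sid in sorted(factors):
        f = factors[sid]
        rows.append({name: getattr(f, name) for name in FACTOR_COLUMNS})
    pd.DataFrame(rows, columns=list(FACTOR_COLUMNS)).to_csv(
        path, sep=sep, index=False)


def write_estimates(estimates: Sequence[DiversityEstimate], path,
                    sep: str = ",") -> None:
    """Write per-species diversity estimates with a ``marker`` column."""
    df = pd.DataFrame([{
        "species_id": e.species_id, "marker": e.marker, "value": e.value,
        "n_studies_or_loci": e.n_studies_or_loci} for e in estimates],
        columns=["species_id", "marker", "value", "n_studies_or_loci"])
    df.to_csv(path, sep=sep, index=False)


def read_estimates(path, sep: str = ",") -> List[DiversityEstimate]:
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ("species_id", "marker", "value",
                          "n_studies_or_loci"), path)
    return [DiversityEstimate(str(r.species_id), str(r.marker),
                              float(r.value), int(r.n_studies_or_loci))
            for r in df.itertuples(index=False)]
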