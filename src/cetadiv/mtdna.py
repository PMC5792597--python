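"""Per-species mitochondrial diversity from published estimates.

Each species' regional (piR) and rangewide (piO) control-region nucleotide
diversity is the unweighted mean of all published estimates based on at
least 100 sequences.  Values are carried in percent throughout.
"""

from __future__ import annotations

from collections import defaultdict
from typing import List, Optional, Sequence

from .errors import DomainError, ValidationError
from .records import SCOPE_TO_PI_MARKER, DiversityEstimate, MtdnaRecord

__all__ = ["classify_scope", "aggregate_pi", "MIN_SAMPLE_SIZE"]

#: Minimum number of sequences for a published pi estimate to count.
MIN_SAMPLE_SIZE = 100


def classify_scope(coverage_fraction: float, whole_basin: bool) -> str:
    """Classify a study as regional or rangewide.

    Rangewide iff the samples cover at least 25% of the species range
    (inclusive bound) or an entire ocean basin.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise DomainError(
            f"coverage_fraction must be in [0, 1], got {coverage_fraction}")
    return "rangewide" if (coverage_fraction >= 0.25 or whole_basin) else "regional"


def aggregate_pi(records: Sequence[MtdnaRecord], scope: Optional[str] = None,
                 min_sample_size: int = MIN_SAMPLE_SIZE
                 ) -> List[DiversityEstimate]:
    """Per-species mean pi over qualifying studies (sample size >= 100).

    Species with no qualifying study are omitted; the number of
    contributing studies is recorded on each estimate.
    """
    records = list(records)
    if scope is None and records:
        scope = records[0].scope
    if any(r.scope != scope for r in records):
        raise ValidationError(
            f"records mix scopes; expected all {scope!r}")
    marker = SCOPE_TO_PI_MARKER[scope] if scope else "piR"
    values = defaultdict(list)
    for r in records:
        if r.sample_size >= min_sample_size:
            values[r.species_id].append(r.pi_percent)
    return [
        DiversityEstimate(species_id=sp, marker=marker,
                          value=sum(v) / len(v), n_studies_or_loci=len(v))
        for sp, v in sorted(values.items())]
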