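"""Exception hierarchy for cetadiv."""


class CetadivError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CetadivError, ValueError):
    """A record or table violates a documented invariant."""


class SchemaError(ValidationError):
    """A delimited file is missing required columns."""


class TreeError(CetadivError, ValueError):
    """A phylogeny is malformed or unusable (missing lengths, bad Newick...)."""


class DomainError(CetadivError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ConvergenceError(CetadivError, RuntimeError):
    """An iterative fit failed to converge.

    Carries the best iterate found so callers can inspect it.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class IdentifiabilityError(CetadivError, ValueError):
    """A model cannot be identified from the data provided (e.g. one species)."""


class RankDeficiencyError(CetadivError, ValueError):
    """A design matrix is rank deficient; names the aliased columns."""

    def __init__(self, message: str, aliased=()):
        super().__init__(message)
        self.aliased = tuple(aliased)


class DegenerateModelError(CetadivError, ValueError):
    """A model fit is degenerate (zero residual variance, empty data...)."""
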