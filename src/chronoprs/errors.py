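"""Exception hierarchy for chronoprs.

Every error raised by the package derives from :class:`ChronoPRSError` so
callers can catch the package's failures with one clause.
"""


class ChronoPRSError(Exception):
    """Base class for all chronoprs errors."""


class ConfigurationError(ChronoPRSError, ValueError):
    """A simulation or analysis configuration field is out of range."""


class SamplingBudgetError(ChronoPRSError, RuntimeError):
    """Liability-threshold rejection sampling exhausted its draw budget."""


class EmptyPanelError(ChronoPRSError, ValueError):
    """Allele harmonization left zero usable variants."""


class ThresholdError(ChronoPRSError, ValueError):
    """A p-value threshold selected zero variants for scoring."""


class DegenerateScoreError(ChronoPRSError, ValueError):
    """A score vector has zero variance and cannot be standardized."""


class DegenerateOutcomeError(ChronoPRSError, ValueError):
    """A transformed outcome has zero variance."""


class ValidationError(ChronoPRSError, ValueError):
    """Input table violates a documented invariant."""


class CollinearityError(ChronoPRSError, ValueError):
    """Rank-deficient regression design; carries the aliased column names."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class ConvergenceError(ChronoPRSError, RuntimeError):
    """Maximum-likelihood optimizer failed to converge."""


class SeparationError(ChronoPRSError, RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class NestingError(ChronoPRSError, ValueError):
    """Log-likelihoods violate the nested-model ordering."""
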