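"""Exception hierarchy for cohortgp."""


class CohortGPError(Exception):
    """Base class for all cohortgp errors."""


class DataError(CohortGPError, ValueError):
    """Non-finite or otherwise invalid numeric data."""


class ShapeError(CohortGPError, ValueError):
    """Dimension or alignment mismatch between arrays."""


class ArgumentError(CohortGPError, ValueError):
    """Invalid argument value (non-positive counts, unknown names, ...)."""


class BudgetError(CohortGPError, ValueError):
    """A requested training-subset size exceeds what is available."""


class LookupError_(CohortGPError, KeyError):
    """Unknown member or output name."""


class CoverageError(CohortGPError, KeyError):
    """A cohort member is missing required side information (e.g. latents)."""


class StateError(CohortGPError, RuntimeError):
    """Operation on an object in the wrong state (e.g. unfitted emulator)."""


class RankError(CohortGPError, ValueError):
    """Degenerate or rank-deficient design where full rank is required."""


class ConditioningError(CohortGPError, RuntimeError):
    """A covariance matrix stayed indefinite after jitter escalation."""


class SchemaError(CohortGPError, ValueError):
    """A data file does not match the documented schema."""
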