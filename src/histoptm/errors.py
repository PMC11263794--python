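"""Exception types shared across the pipeline."""


class HistoptmError(Exception):
    """Base class for all package errors."""


class InvalidSequenceError(HistoptmError):
    """A protein or peptide sequence contains a non-standard residue or is empty."""


class InvalidModificationError(HistoptmError):
    """A modification is placed on an incompatible residue or outside the peptide."""


class SchemaError(HistoptmError):
    """An input table is missing required fields."""


class InvalidDataError(HistoptmError):
    """A record carries an impossible value (e.g. negative peak area)."""


class ConsistencyError(HistoptmError):
    """Cross-references between tables do not resolve."""


class ConfigError(HistoptmError):
    """A run configuration is invalid."""


class MustImputeFirstError(HistoptmError):
    """A log-ratio transform was applied to a composition containing zeros."""


class DegenerateNullError(HistoptmError):
    """A binomial null probability of exactly 0 or 1 was supplied."""


class UndefinedRatioError(HistoptmError):
    """A ratio with a zero denominator was requested."""


class SingularCovarianceError(HistoptmError):
    """Pooled covariance is singular; reduce dimension before testing."""
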