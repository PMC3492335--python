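"""Named validation and analysis errors.

Readers reject rather than silently coerce; every error message should
carry enough context (file, line, field) to locate the offending record.
"""


class TriomicsError(Exception):
    """Base class for all package errors."""


class ValidationError(TriomicsError, ValueError):
    """Malformed or inconsistent input data."""


class MalformedRowError(ValidationError):
    """A TSV row does not match the expected dialect."""


class DuplicateIdError(ValidationError):
    """Duplicate gene, probe or sample identifiers."""


class BetaRangeError(ValidationError):
    """A beta value outside [0, 1]."""


class SegmentOverlapError(ValidationError):
    """Overlapping segments on one chromosome of one track."""


class SexChromosomeError(ValidationError):
    """A record on a non-autosomal chromosome (only chr1-22 admitted)."""


class CoordinateError(ValidationError):
    """Interval with end <= start or negative coordinates."""


class MissingControlError(ValidationError):
    """A designated control column is absent from the matrix."""


class ConfigurationError(TriomicsError, ValueError):
    """An unsatisfiable or invalid configuration."""


class NotEstimableError(TriomicsError):
    """A statistic cannot be computed on the given input (degenerate scope)."""
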