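"""Typed exceptions raised by validated readers and pipeline stages."""


class MemoryScreenError(Exception):
    """Base class for all package-specific errors."""


class DataValidationError(MemoryScreenError, ValueError):
    """Input data violates a documented invariant."""


class NonNumericValueError(DataValidationError):
    """A cell that must be numeric could not be parsed as a number."""


class NegativeValueError(DataValidationError):
    """A TPM expression value was negative."""


class DuplicateIdentifierError(DataValidationError):
    """Gene or sample identifiers are not unique."""


class MissingColumnError(DataValidationError):
    """A required column is absent from a tabular input."""


class InvalidEventError(DataValidationError):
    """A survival event indicator is outside {0, 1}."""


class NonPositiveTimeError(DataValidationError):
    """A follow-up time is zero or negative."""


class AlignmentError(DataValidationError):
    """Expression and survival tables share too few samples."""


class ConfigError(MemoryScreenError, ValueError):
    """A run configuration key is unknown or out of range."""
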