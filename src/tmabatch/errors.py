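"""Exception hierarchy shared across the package.

Errors are deliberately specific so that pipeline callers can distinguish
malformed input (schema/integrity), statistically infeasible designs
(design), and numerical failures (estimation).
"""


class TmaBatchError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TmaBatchError):
    """A required column is missing or has the wrong type."""


class IntegrityError(TmaBatchError):
    """Key constraints violated (duplicate keys, inconsistent batches)."""


class ParseError(TmaBatchError):
    """A value could not be parsed; carries the offending row number."""


class DomainError(TmaBatchError):
    """A transform was requested outside its mathematical domain."""


class DesignError(TmaBatchError):
    """The data layout cannot support the requested model."""


class EstimationError(TmaBatchError):
    """Model fitting failed in a way that has no useful partial result."""


class ConfigurationError(TmaBatchError):
    """A scenario or run configuration is internally inconsistent."""


class AlignmentError(TmaBatchError):
    """Two results do not cover the same sample/marker keys."""
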