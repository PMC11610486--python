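"""Exception hierarchy shared across the package."""


class NanozetaError(Exception):
    """Base class for all package errors."""


class SchemaError(NanozetaError):
    """A required column is missing or a table violates the canonical schema."""


class ParseError(NanozetaError):
    """A cell or formula string could not be parsed."""


class IntegrityError(NanozetaError):
    """Duplicate ids, overlapping splits, or other dataset-level violations."""


class DomainError(NanozetaError):
    """A numeric argument is outside its mathematical domain."""


class FitError(NanozetaError):
    """A model could not be fitted (rank deficiency, degenerate design, ...)."""


class ConfigurationError(NanozetaError):
    """A model or pipeline configuration is incomplete or inconsistent."""
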