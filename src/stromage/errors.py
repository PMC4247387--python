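"""Typed error hierarchy.

Every anticipated failure mode raises a subclass of :class:`StromageError`
so callers can distinguish bad input files (``ParseError``), tables that do
not match the cohort design (``SchemaError``), values that violate a
contract (``ValidationError``), and impossible configurations
(``ConfigurationError``).
"""


class StromageError(Exception):
    """Base class for all package errors."""


class ParseError(StromageError):
    """A delimited-text input could not be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SchemaError(StromageError):
    """Columns / sample ids do not match the cohort design."""


class ValidationError(StromageError):
    """Values violate an invariant (negative intensity, duplicate id, ...)."""


class ConfigurationError(StromageError):
    """An analysis or simulation parameter set is infeasible."""
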