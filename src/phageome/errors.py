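"""Exception hierarchy for the phageome pipeline."""


class PhageomeError(Exception):
    """Base class for all package errors."""


class ConfigError(PhageomeError):
    """A configuration value is invalid; the message names the offending field."""


class ParameterError(PhageomeError):
    """An operation was called with an unusable parameter."""


class DataError(PhageomeError):
    """Input data violates a structural precondition (bounds, totals, missing rows)."""


class ParseError(PhageomeError):
    """A file could not be parsed; carries a line number where possible."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class GenerationError(PhageomeError):
    """The synthetic-data generator could not satisfy a placement request."""
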