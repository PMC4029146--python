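"""Exception hierarchy shared across the package."""


class RertdoseError(Exception):
    """Base class for all package errors."""


class ValidationError(RertdoseError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(RertdoseError, ValueError):
    """A model parameter is outside its admissible range."""


class DataError(RertdoseError, ValueError):
    """Patient-level input data are inconsistent (e.g. death before treatment)."""


class ParseError(RertdoseError, ValueError):
    """A file could not be parsed; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
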