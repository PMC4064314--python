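"""Exception hierarchy shared across the package."""


class TransficError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TransficError):
    """A run was configured inconsistently (missing column, unknown tool, empty input)."""


class ParseError(TransficError):
    """An input file violates its format contract.

    Parameters
    ----------
    message : str
        Human-readable description.
    line : int, optional
        1-based line number of the offending record, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DomainError(TransficError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class CalibrationError(TransficError):
    """Category-boundary calibration produced no usable (low, high) pair."""
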