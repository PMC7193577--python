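"""Exception types shared across the package."""


class DendrintError(Exception):
    """Base class for package-specific errors."""


class InvalidArgumentError(DendrintError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class GenerationFailureError(DendrintError, RuntimeError):
    """A synthetic generator could not reach its target after max retries."""


class UndefinedMetricError(DendrintError, ArithmeticError):
    """A metric is mathematically undefined for the given input
    (zero denominator, zero-length vector, degenerate geometry)."""


class ParseError(DendrintError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
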