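"""Exception hierarchy shared across the package."""


class PtwasError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PtwasError, ValueError):
    """A malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(PtwasError, ValueError):
    """An input violates a documented invariant (duplicate ids, bad shapes...)."""


class WeakInstrumentError(PtwasError, ValueError):
    """The eQTL effect is numerically indistinguishable from zero."""


class UndefinedTestError(PtwasError, ValueError):
    """The test statistic is undefined (e.g., zero-variance composite IV)."""


class NotEstimable(PtwasError):
    """A gene has no eligible instrument; a signal, not a failure."""
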