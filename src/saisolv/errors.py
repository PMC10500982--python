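"""Exception hierarchy shared across the package."""


class SaisolvError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SaisolvError):
    """A structured text input could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(SaisolvError):
    """An object violates one of its documented invariants."""


class ConvergenceError(SaisolvError):
    """An iterative solver failed to converge.

    ``diagnostics`` holds whatever the solver could compute (for MBAR,
    the state-overlap matrix at the last iterate).
    """

    def __init__(self, message: str, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)


class OverlapWarning(UserWarning):
    """Adjacent alchemical states have poor phase-space overlap."""
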