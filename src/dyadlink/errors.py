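"""Exception hierarchy shared across the package."""


class DyadlinkError(Exception):
    """Base class for all package-specific errors."""


class TranscriptParseError(DyadlinkError):
    """A transcript line or record could not be interpreted."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(DyadlinkError):
    """Input source contained no usable content."""


class EmptyStreamError(DyadlinkError):
    """A token stream was requested for a role with no tokens."""


class InsufficientLengthError(DyadlinkError):
    """A sequence is too short for the requested computation."""


class DegenerateInputError(DyadlinkError):
    """Zero-variance or otherwise degenerate numeric input."""


class SpecError(DyadlinkError):
    """An infeasible or inconsistent simulation specification."""


class ConfigurationError(DyadlinkError):
    """A run or policy configuration is incomplete or invalid."""


class InvariantViolationError(DyadlinkError):
    """A domain invariant (e.g., repayment bounds) was violated."""


class JoinError(DyadlinkError):
    """Feature and outcome tables do not share the same dyads."""

    def __init__(self, message: str, offenders=()):
        self.offenders = list(offenders)
        super().__init__(message)
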