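"""Exception hierarchy used across the package.

Parse errors, invalid arguments and degenerate inputs are distinguished so
the CLI can map them to distinct exit codes.
"""


class OsnCisTransError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(OsnCisTransError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(OsnCisTransError, ValueError):
    """Input is structurally valid but degenerate for the requested computation."""


class GateFailureError(DegenerateInputError):
    """No marker gene survived the correlation gate."""


class UndefinedStatisticError(DegenerateInputError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ParseError(OsnCisTransError, ValueError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
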