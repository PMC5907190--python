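"""Exception hierarchy for ecinet.

All ecinet-specific failures derive from :class:`EcinetError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class EcinetError(Exception):
    """Base class for all ecinet errors."""


class NetworkParseError(EcinetError):
    """A network document is syntactically malformed.

    Carries the 1-based line number (TSV dialect) or JSON path when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NetworkValidationError(EcinetError):
    """A parsed network violates a structural invariant."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class CapacityError(EcinetError):
    """An exhaustive enumeration would exceed its configured cap."""


class GenerationError(EcinetError):
    """A random-network generator configuration is infeasible."""


class ReductionError(EcinetError):
    """A graph cannot be reduced (e.g. isolated vertex: no edge cover)."""


class SolverError(EcinetError):
    """The MILP backend is unavailable or failed unexpectedly."""
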