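"""Package-level exception types."""


class Hsp90KitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(Hsp90KitError, ValueError):
    """Malformed or out-of-domain input."""


class ConvergenceError(Hsp90KitError, RuntimeError):
    """An iterative solver exhausted its iteration budget.

    Carries the last residual so callers can judge how far off it was.
    """

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DisconnectedWindowsError(Hsp90KitError, ValueError):
    """Umbrella windows form histogram groups with no mutual overlap."""
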