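"""Exception hierarchy for the co-contagion model package."""


class CocontagionError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CocontagionError, ValueError):
    """A parameter value violates the model's domain constraints.

    Carries the offending field name in ``field`` when known.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class UnknownParameterError(InvalidParameterError):
    """A configuration file contains a key that is not a model parameter."""


class NoEndemicEquilibriumError(CocontagionError):
    """Requested an endemic equilibrium where none exists (R0 <= 1)."""


class ConvergenceError(CocontagionError):
    """An iterative solver (ODE integrator or root finder) failed to converge."""


class InvariantViolationError(CocontagionError):
    """A computed trajectory breached positivity or boundedness beyond tolerance.

    ``diagnostics`` holds a dict with the worst offending value, its time and
    compartment, so that solver misconfiguration is surfaced rather than
    silently clipped.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
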