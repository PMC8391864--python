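"""Exception hierarchy shared across the package."""


class IfflPulseError(Exception):
    """Base class for all package errors."""


class ParameterError(IfflPulseError, ValueError):
    """A kinetic parameter, Hill constant or option is outside its domain."""


class StateDomainError(IfflPulseError, ValueError):
    """A model state violates an invariant (negative species, PZ_rep > P_Z_total)."""


class IntegrationError(IfflPulseError, RuntimeError):
    """The ODE solver failed; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class SchemaError(IfflPulseError, ValueError):
    """A plate-reader table or config file does not match the documented schema."""


class AnalysisError(IfflPulseError, ValueError):
    """An analysis precondition is not met (empty window, all-blank plate, ...)."""
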