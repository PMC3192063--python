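"""Exception hierarchy for wntclock."""


class WntClockError(Exception):
    """Base class for all wntclock errors."""


class InvalidParameterError(WntClockError, ValueError):
    """A kinetic parameter is out of its admissible domain."""


class StateDomainError(WntClockError, ValueError):
    """A concentration is negative beyond the numerical tolerance."""


class ConfigurationError(WntClockError, ValueError):
    """A scenario, schedule or scan request is malformed."""


class IntegrationError(WntClockError, RuntimeError):
    """The ODE solver failed before reaching the requested end time."""

    def __init__(self, message: str, failing_time: float | None = None):
        super().__init__(message)
        self.failing_time = failing_time


class InsufficientDataError(WntClockError, ValueError):
    """A time series is too short for the requested measurement."""
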