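"""Exception hierarchy for the simulator."""

from __future__ import annotations


class VenapumpError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(VenapumpError, ValueError):
    """A physical or numerical parameter is out of its admissible range."""


class CalibrationError(VenapumpError):
    """A calibration target cannot be met (e.g. negative porous resistance)."""


class DiscretizationError(VenapumpError):
    """The requested grid cannot be built (e.g. dx larger than a segment)."""


class StabilityError(VenapumpError):
    """The requested time step violates the stability contract."""


class NumericalFailureError(VenapumpError):
    """The solver produced a non-finite state.

    Attributes
    ----------
    last_valid_time : float
        Simulation time (s) of the last finite state.
    """

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time


class StateViolationError(VenapumpError):
    """A dynamic state (e.g. ball position) violates its bounds."""


class InsufficientDataError(VenapumpError):
    """A time series is too short for the requested metric."""


class ComparisonError(VenapumpError):
    """Scenario comparison is missing its baseline."""


class ConfigurationError(VenapumpError):
    """A run configuration failed validation.

    Attributes
    ----------
    violations : list[str]
        Complete list of violations (not fail-fast).
    """

    def __init__(self, message: str, violations: list[str] | None = None):
        super().__init__(message)
        self.violations = violations or []
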