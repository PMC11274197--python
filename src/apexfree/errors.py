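"""Exception hierarchy for the apexfree simulator."""


class ApexfreeError(Exception):
    """Base class for all package errors."""


class GeometryError(ApexfreeError):
    """Degenerate or inconsistent ventricular geometry."""


class MaterialError(ApexfreeError):
    """Non-physical material parameters or kinematic state."""


class ConvergenceError(ApexfreeError):
    """Nonlinear equilibrium solve failed to converge.

    Carries the last residual norm in ``residual`` when available.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class CirculationError(ApexfreeError):
    """Lumped-circulation integration failure (e.g. negative chamber volume)."""


class CalibrationError(ApexfreeError):
    """Baseline calibration targets unreachable within bounds."""


class PostprocessError(ApexfreeError):
    """Inconsistent inputs to a post-processing metric."""
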