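"""Exception hierarchy for the oculoplant package."""


class OculoplantError(Exception):
    """Base class for all package errors."""


class ValidationError(OculoplantError):
    """A configuration file or object violates the documented schema."""


class InvariantError(OculoplantError):
    """A physical invariant of the model is violated (e.g. insertion off globe)."""


class ParameterError(OculoplantError, ValueError):
    """An operation was called with an out-of-range parameter."""


class ConvergenceError(OculoplantError):
    """A static solve or calibration failed to converge; carries residuals."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals or {}


class DivergenceError(OculoplantError):
    """Numerical integration blew up (instability detector tripped)."""
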