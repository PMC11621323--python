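"""Exception hierarchy for the fluctuodyn pipeline."""


class FluctuodynError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FluctuodynError, ValueError):
    """A physical parameter is outside its admissible range."""


class PlacementFailureError(FluctuodynError, RuntimeError):
    """Hard-sphere insertion failed within the iteration budget."""


class InsufficientDataError(FluctuodynError, ValueError):
    """Not enough particles / points to carry out the operation."""


class UnsupportedGeometryError(FluctuodynError, ValueError):
    """The simulation cell is not an orthorhombic box."""


class FitFailureError(FluctuodynError, RuntimeError):
    """A nonlinear least-squares fit failed to converge.

    Carries the initial values and residual norm so the caller can
    diagnose the failure.
    """

    def __init__(self, message, initial_values=None, residual_norm=None):
        super().__init__(message)
        self.initial_values = initial_values
        self.residual_norm = residual_norm


class IncompatibleGridsError(FluctuodynError, ValueError):
    """Curves do not share an overlapping q range."""


class NoCrossingError(FluctuodynError, RuntimeError):
    """A population fraction never crosses 1/2 within the data range."""


class IntegrationAbortError(FluctuodynError, RuntimeError):
    """Droplet integration reached a nonphysical state; carries the last valid state."""

    def __init__(self, message, last_state=None):
        super().__init__(message)
        self.last_state = last_state


class CurveIOError(FluctuodynError, ValueError):
    """A curve or configuration file could not be parsed."""

    def __init__(self, message, line_number=None):
        super().__init__(message)
        self.line_number = line_number
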