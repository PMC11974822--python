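"""Exception types shared across the package."""


class PauseKineticsError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(PauseKineticsError, ValueError):
    """A rate, density or ratio violates its domain (e.g. negative rate)."""


class DegenerateSteadyStateError(PauseKineticsError, ValueError):
    """Steady state undefined because the total pause exit rate is zero."""


class UnscaledDensityError(PauseKineticsError, ValueError):
    """An absolute-rate computation received densities not scaled to occupancy."""


class ClampError(PauseKineticsError, ValueError):
    """Initiation fold-change clamping could not place the value inside its bounds."""


class SaturationFitError(PauseKineticsError, RuntimeError):
    """The tanh saturation fit failed or produced a degenerate result."""
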