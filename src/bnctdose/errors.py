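"""Exception hierarchy shared across the package."""


class BnctDoseError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BnctDoseError, ValueError):
    """A model parameter is outside its admissible range."""


class InvalidInputError(BnctDoseError, ValueError):
    """An input quantity (dose, time, survival level) is invalid."""


class InsufficientDataError(BnctDoseError, ValueError):
    """Too few data points for the requested fit."""


class ConvergenceError(BnctDoseError, RuntimeError):
    """An iterative fit or solver failed to converge."""


class IdentifiabilityError(BnctDoseError, ValueError):
    """The requested parameters are not identifiable from the supplied data."""


class RegistrationError(BnctDoseError, ValueError):
    """Volumetric inputs are not co-registered (shape/spacing/origin mismatch)."""


class InvalidMaskError(BnctDoseError, ValueError):
    """A region-of-interest mask is empty or incompatible with the grid."""


class UnboundedTimeError(BnctDoseError, ValueError):
    """A prescription cannot bound the irradiation time (zero dose rate in ROI)."""


class ConfigError(BnctDoseError, ValueError):
    """A pipeline configuration is invalid or references missing files."""
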