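"""Exception types shared across the pipeline stages."""


class MPMBreastError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MPMBreastError, ValueError):
    """A configuration value violates its invariant."""


class PlacementError(MPMBreastError, RuntimeError):
    """Phantom structures could not be placed within the overlap budget."""


class CalibrationError(MPMBreastError, RuntimeError):
    """No z-plane reached the required signal coverage."""


class DegenerateChannelError(MPMBreastError, ValueError):
    """A channel is constant and cannot be standardized; route to blank handling."""


class GeometryError(MPMBreastError, ValueError):
    """Image/tile dimensions are inconsistent."""


class DataError(MPMBreastError, ValueError):
    """A manifest or tile record is missing required fields."""


class DegenerateTrainingError(MPMBreastError, ValueError):
    """Training data contains a single class."""
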