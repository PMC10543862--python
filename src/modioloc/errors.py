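"""Exception hierarchy.

``ConfigError`` covers bad user configuration; ``DataError`` subclasses cover
defects in the measurement data itself. The CLI maps these onto distinct exit
codes (config 2, data 3, internal 1).
"""


class ModiolocError(Exception):
    """Base class for all package errors."""


class ConfigError(ModiolocError):
    """Invalid configuration (simulation parameters, pipeline options, files)."""


class DataError(ModiolocError):
    """Base class for errors caused by the content of measurement data."""


class InvalidMeasurementError(DataError):
    """A measurement violates the data model (non-positive EMD, bad ordering...)."""


class DegeneratePositionError(DataError):
    """An electrode coincides with the candidate axis; its angle is undefined."""


class PairingError(DataError):
    """Two measurement sets do not cover the same (array, electrode) pairs."""


class UndefinedCorrelationError(DataError):
    """Pearson correlation requested on a zero-variance sequence."""


class InsufficientDataError(DataError):
    """Too few observations for the requested statistic."""


class IncompleteMatrixError(DataError):
    """A ratings matrix with missing cells was passed to the ICC."""


class InvalidReferenceError(DataError):
    """Percentage error requested against a non-positive reference mean."""
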