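"""Exception hierarchy for the pointillism package."""


class PointillismError(Exception):
    """Base class for package errors."""


class DomainError(PointillismError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ConfigurationError(PointillismError, ValueError):
    """A calibration or configuration object is internally inconsistent."""


class DegeneratePairError(PointillismError, ValueError):
    """A colour pair with identical endpoints has no transition structure."""


class GeometryError(PointillismError, ValueError):
    """A point set is too degenerate for a Voronoi tessellation."""


class FillCalibrationError(PointillismError, RuntimeError):
    """The requested uncovered fraction cannot be reached by scaling dot radii."""


class FittingError(PointillismError, ValueError):
    """The design matrix for a model fit is rank deficient or empty."""


class InsufficientDataError(PointillismError, ValueError):
    """Too few matched cells or observers for the requested statistic."""


class SchemaError(PointillismError, ValueError):
    """A tabular file does not conform to the expected column schema."""
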