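"""Exception hierarchy used across the pipeline."""


class VidRadiomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(VidRadiomicsError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InputError(VidRadiomicsError, ValueError):
    """Malformed or empty input data."""


class DegenerateROIError(VidRadiomicsError, ValueError):
    """An ROI is empty or otherwise unusable for feature extraction."""


class DegenerateTrackError(VidRadiomicsError, ValueError):
    """A box track has too few observed boxes to be repaired."""


class ShortSeriesError(VidRadiomicsError, ValueError):
    """A feature trajectory is too short for time/frequency analysis."""


class DegenerateLabelError(VidRadiomicsError, ValueError):
    """Training labels contain a single class."""


class CohortTooSmallError(VidRadiomicsError, ValueError):
    """Too few cases to split into train and test cohorts."""


class ShapeError(VidRadiomicsError, ValueError):
    """Array shapes or column sets do not match."""


class UndefinedMetricError(VidRadiomicsError, ValueError):
    """A performance metric is undefined for the given predictions."""


class CIError(VidRadiomicsError, RuntimeError):
    """A bootstrap confidence interval could not be computed."""
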