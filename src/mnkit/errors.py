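"""Exception and warning types raised across the pipeline."""


class MnkitError(Exception):
    """Base class for all package errors."""


class UnresolvableWaveformError(MnkitError):
    """Stimulus period too short to be represented at the sampling interval."""


class DensityInfeasibleError(MnkitError):
    """Requested cell count cannot be packed at the minimum separation."""


class UnknownPresetError(MnkitError):
    """Preset name not found in the registry."""


class GeometryError(MnkitError):
    """Chamber / grid geometry degenerate for the requested operation."""


class DegenerateFieldError(MnkitError):
    """Vector-field grid too small for spatial statistics."""


class TriangulationError(MnkitError):
    """Fewer than three non-collinear cells; no triangulation exists."""


class CalibrationError(MnkitError):
    """Missing physical calibration (e.g. pixel size) for an image operation."""


class NoOscillatoryPowerError(MnkitError):
    """Constant trace: dominant frequency undefined."""


class BandError(MnkitError):
    """Requested frequency band empty or outside (0, Nyquist]."""


class UndefinedCorrelationError(MnkitError):
    """Zero-variance trace: Pearson correlation undefined."""


class EmptySummaryError(MnkitError):
    """No valid pairs / entities to summarize."""


class BaselineWindowError(MnkitError):
    """Pre-stimulus baseline window empty or absent from the record."""


class AmbiguousCalibrationWarning(UserWarning):
    """Evaluator non-monotone on the calibration grid; argmin still returned."""


class EmptyOutputWarning(UserWarning):
    """Filtering removed every track / trace."""
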