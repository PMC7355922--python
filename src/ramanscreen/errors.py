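"""Exception hierarchy.

All user-facing failures derive from :class:`RamanScreenError` so the CLI can
separate user errors (exit code 1) from internal bugs (exit code 2).
"""


class RamanScreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RamanScreenError):
    """A file does not follow the documented CSV dialect."""


class ConsistencyError(RamanScreenError):
    """Spectra table and lesion manifest disagree about measurement ids."""


class GridError(RamanScreenError):
    """Wavenumber grids are inconsistent or non-monotone."""


class ConfigError(RamanScreenError):
    """A configuration value is out of its valid range."""


class ShapeError(RamanScreenError):
    """Array shapes do not match."""


class CalibrationError(RamanScreenError):
    """Invalid intensity-response calibration input."""


class RangeError(RamanScreenError):
    """A spectral crop produced too few points."""


class NormalizationError(RamanScreenError):
    """Area normalization is impossible (zero or negative area)."""


class PreprocessError(RamanScreenError):
    """A preprocessing stage failed; carries the measurement id."""


class FitError(RamanScreenError):
    """Model fitting failed (single class, non-convergence)."""


class EvaluationError(RamanScreenError):
    """ROC / screening metrics cannot be computed on this input."""


class DomainError(RamanScreenError):
    """A scalar argument is outside its mathematical domain."""


class ReportError(RamanScreenError):
    """A run directory is missing artifacts required for reporting."""
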