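"""Exception hierarchy.

All package errors derive from :class:`ChromacalError` so callers (and the
CLI) can map failures to exit codes: usage problems are left to the CLI
framework, quality-gate failures get their own class, everything else is a
data/format error.
"""


class ChromacalError(Exception):
    """Base class for all chromacal errors."""


class GridMismatchError(ChromacalError):
    """Spectral quantities defined on different wavelength grids were mixed."""


class LayoutError(ChromacalError):
    """A card layout cannot hold the requested patches."""


class PatternError(ChromacalError):
    """Unknown or unsupported color filter array pattern."""


class MetadataError(ChromacalError):
    """A required frame metadata field is missing or invalid."""


class ROIError(ChromacalError):
    """Empty or mismatched region of interest."""


class SaturationError(ROIError):
    """Too large a fraction of an ROI is saturated for statistics to be trusted."""


class PairingError(ChromacalError):
    """Flash and no-flash frames are not a valid pair (exposure/ISO/shape mismatch)."""


class SubtractionError(ChromacalError):
    """Ambient subtraction produced a non-positive component (flash did not dominate)."""


class SSNRUndefinedError(ChromacalError):
    """SSNR is undefined because both signals are zero."""


class QualityGateError(ChromacalError):
    """An image pair failed the SSNR quality gate."""


class IntensityError(ChromacalError):
    """Grey-card intensity extraction produced a non-positive patch value."""


class AlignmentError(ChromacalError):
    """Patch id sets of two inputs do not align."""


class ConditioningError(ChromacalError):
    """Design matrix is rank deficient or too ill-conditioned to fit."""


class DegenerateColorError(ChromacalError):
    """Chromaticity undefined: channel sum is not positive."""


class InsufficientDataError(ChromacalError):
    """Not enough repeats/sessions to compute the requested statistic."""
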