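"""Flash/no-flash ambient subtraction and the SSNR capture-quality metric.

Because flash and ambient light add at the photon level, subtracting the
no-flash capture from the flash capture (taken at identical exposure time
and ISO) leaves a signal lit only by the flash — a standardized illumination
that makes sessions under different ambient light comparable. Subtraction is
performed on per-ROI statistics, not per pixel, so small motion between the
two captures does not corrupt the result.

The Subtracted Signal-to-Noise Ratio quantifies whether the flash dominated:

    SSNR = (S_F+A − S_A) / sqrt(S_F+A + S_A)

with S the ROI-mean signals of the two frames on the black-level-subtracted
raw scale, where shot noise follows Poisson statistics and errors add in
quadrature. Captures below the threshold (default 3.4) should be retaken.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PairingError, SSNRUndefinedError, SubtractionError
from .frames import BayerFrame, demosaic, linearize, roi_mean_rgb, roi_median_rgb

__all__ = [
    "DEFAULT_SSNR_THRESHOLD",
    "PairMeasurement",
    "SSNRReport",
    "subtract_pair",
    "compute_ssnr",
    "quality_gate",
    "measure_pair",
]

#: Default SSNR below which an image pair should be retaken.
DEFAULT_SSNR_THRESHOLD = 3.4


@dataclass(frozen=True)
class PairMeasurement:
    """ROI color measurement from one flash/no-flash pair."""

    f_flash_ambient: np.ndarray  # ROI median RGB of the flash frame
    f_ambient: np.ndarray  # ROI median RGB of the no-flash frame
    f_flash_only: np.ndarray  # subtracted, flash-only RGB
    ssnr: float
    roi_id: str = ""
    device_id: str = ""


@dataclass(frozen=True)
class SSNRReport:
    """Outcome of the capture-quality gate for one ROI."""

    ssnr: float
    threshold: float
    passed: bool
    flash_signal_mean: float
    ambient_signal_mean: float


def subtract_pair(flash_median: np.ndarray, ambient_median: np.ndarray) -> np.ndarray:
    """Componentwise flash − ambient on ROI medians; every component must be > 0.

    A non-positive component means the flash did not dominate that channel
    (or the ambient changed between frames); the protocol treats both as a
    retake condition, so this raises instead of clamping.
    """
    flash_median = np.asarray(flash_median, dtype=float)
    ambient_median = np.asarray(ambient_median, dtype=float)
    diff = flash_median - ambient_median
    if np.any(diff <= 0):
        raise SubtractionError(
            f"non-positive subtracted component {diff}; flash did not dominate "
            "or the frames are mismatched — retake the pair"
        )
    return diff


def compute_ssnr(flash_mean_rgb, ambient_mean_rgb) -> float:
    """Global SSNR from demosaiced ROI means on the black-level-subtracted scale.

    The three channel means of each frame are averaged into one scalar signal
    (demosaiced data weights the channels equally), then
    SSNR = (S_F − S_A) / sqrt(S_F + S_A). A negative value (ambient mean
    exceeding flash mean) is returned with a warning: the pair is unusable.
    """
    s_f = float(np.mean(np.asarray(flash_mean_rgb, dtype=float)))
    s_a = float(np.mean(np.asarray(ambient_mean_rgb, dtype=float)))
    total = s_f + s_a
    if total == 0:
        raise SSNRUndefinedError("both signals are zero; SSNR undefined")
    ssnr = (s_f - s_a) / math.sqrt(total)
    if ssnr < 0:
        warnings.warn(
            "flash ROI mean below no-flash ROI mean; retake the pair", stacklevel=2
        )
    return ssnr


def _require_pair(flash: BayerFrame, noflash: BayerFrame) -> None:
    if flash.exposure_time != noflash.exposure_time:
        raise PairingError(
            "exposure time differs between frames; ambient subtraction requires "
            "exposure time and ISO be kept fixed"
        )
    if flash.iso_scale != noflash.iso_scale:
        raise PairingError("ISO differs between frames")
    if flash.shape != noflash.shape:
        raise PairingError("frame shapes differ")
    if flash.device_id != noflash.device_id:
        raise PairingError("frames come from different devices")


def quality_gate(
    flash: BayerFrame,
    noflash: BayerFrame,
    roi: np.ndarray,
    threshold: float = DEFAULT_SSNR_THRESHOLD,
) -> SSNRReport:
    """Demosaic both frames, compute ROI-mean signals and gate on SSNR."""
    _require_pair(flash, noflash)
    img_f = demosaic(linearize(flash))
    img_a = demosaic(linearize(noflash))
    mean_f = roi_mean_rgb(img_f, roi)
    mean_a = roi_mean_rgb(img_a, roi)
    ssnr = compute_ssnr(mean_f, mean_a)
    return SSNRReport(
        ssnr=ssnr,
        threshold=threshold,
        passed=ssnr >= threshold,
        flash_signal_mean=float(np.mean(mean_f)),
        ambient_signal_mean=float(np.mean(mean_a)),
    )


def measure_pair(
    flash: BayerFrame,
    noflash: BayerFrame,
    roi: np.ndarray,
    roi_id: str = "",
) -> PairMeasurement:
    """Full ROI measurement of a pair: medians for color, means for SSNR.

    Median statistics drive the color value (robust to outliers and small
    motion); mean statistics drive the SSNR, matching its shot-noise model.
    """
    _require_pair(flash, noflash)
    img_f = demosaic(linearize(flash))
    img_a = demosaic(linearize(noflash))
    med_f = roi_median_rgb(img_f, roi)
    med_a = roi_median_rgb(img_a, roi)
    ssnr = compute_ssnr(roi_mean_rgb(img_f, roi), roi_mean_rgb(img_a, roi))
    return PairMeasurement(
        f_flash_ambient=med_f,
        f_ambient=med_a,
        f_flash_only=subtract_pair(med_f, med_a),
        ssnr=ssnr,
        roi_id=roi_id,
        device_id=flash.device_id,
    )
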