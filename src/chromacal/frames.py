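"""Raw Bayer frame handling: ingest, linearize, demosaic, ROI statistics.

A frame is a single color-filter-array mosaic of digital numbers (DN) plus
the metadata that the ambient-subtraction protocol requires to be held fixed
between the flash and no-flash exposures (exposure time, ISO). Processing is
deliberately minimal and linear: black-level subtraction, bilinear channel
interpolation, robust per-ROI statistics. Anything non-linear (tone curves,
white balance, compression) would break the physics the pipeline relies on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import (
    ChromacalError,
    MetadataError,
    PatternError,
    ROIError,
    SaturationError,
)

__all__ = [
    "CFA_PATTERNS",
    "BayerFrame",
    "LinearMosaic",
    "RGBImage",
    "rect_mask",
    "linearize",
    "demosaic",
    "roi_median_rgb",
    "roi_mean_rgb",
    "write_fixture",
    "read_fixture",
    "read_raw_container",
    "load_roi_layout",
    "save_roi_layout",
]

#: 2×2 CFA tiles, reading order left-to-right then top-to-bottom;
#: channel indices 0=R, 1=G, 2=B.
CFA_PATTERNS = {
    "RGGB": (0, 1, 1, 2),
    "BGGR": (2, 1, 1, 0),
    "GRBG": (1, 0, 2, 1),
    "GBRG": (1, 2, 0, 1),
}

#: Fraction of saturated ROI pixels above which statistics warn / refuse.
SATURATION_WARN_FRACTION = 0.01
SATURATION_ERROR_FRACTION = 0.10


def cfa_channel_map(shape: tuple[int, int], cfa_pattern: str) -> np.ndarray:
    """Per-pixel channel index (0/1/2) for a mosaic of the given shape."""
    try:
        a, b, c, d = CFA_PATTERNS[cfa_pattern]
    except KeyError:
        raise PatternError(f"unknown CFA pattern {cfa_pattern!r}") from None
    tile = np.array([[a, b], [c, d]], dtype=np.int8)
    reps = ((shape[0] + 1) // 2, (shape[1] + 1) // 2)
    return np.tile(tile, reps)[: shape[0], : shape[1]]


@dataclass(frozen=True)
class BayerFrame:
    """One raw mosaic capture plus the metadata needed to pair and linearize it.

    ``dn`` is integer for stochastic captures; noiseless simulation stores
    unquantized float DN so closed-form checks are exact.
    """

    dn: np.ndarray
    cfa_pattern: str
    black_level: float
    white_level: float
    exposure_time: float
    iso_scale: float
    device_id: str = ""
    flash_on: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.dn)
        if arr.ndim != 2:
            raise MetadataError("frame DN array must be 2-D")
        if arr.shape[0] % 2 or arr.shape[1] % 2:
            raise MetadataError("frame dimensions must be even")
        if self.cfa_pattern not in CFA_PATTERNS:
            raise PatternError(f"unknown CFA pattern {self.cfa_pattern!r}")
        if not 0 <= self.black_level < self.white_level:
            raise MetadataError("require 0 <= black_level < white_level")
        if self.exposure_time <= 0 or self.iso_scale <= 0:
            raise MetadataError("exposure_time and iso_scale must be positive")
        if arr.min() < 0 or arr.max() > self.white_level:
            raise MetadataError("DN values must lie in [0, white_level]")
        object.__setattr__(self, "dn", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dn.shape

    def channel_map(self) -> np.ndarray:
        return cfa_channel_map(self.shape, self.cfa_pattern)


@dataclass(frozen=True)
class LinearMosaic:
    """Black-level-subtracted mosaic on a linear scale, with saturation flags."""

    values: np.ndarray
    saturation_mask: np.ndarray
    cfa_pattern: str
    exposure_time: float
    iso_scale: float
    device_id: str = ""
    flash_on: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RGBImage:
    """Three co-registered linear channel planes after demosaicing."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    saturation_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ChromacalError("RGB channels must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.r.shape

    def stack(self) -> np.ndarray:
        """(3, H, W) channel stack in R, G, B order."""
        return np.stack([self.r, self.g, self.b])


def rect_mask(shape: tuple[int, int], rect: tuple[int, int, int, int]) -> np.ndarray:
    """Boolean mask for a (x0, y0, width, height) rectangle, 0-based half-open."""
    x0, y0, w, h = rect
    if w <= 0 or h <= 0:
        raise ROIError("rectangle width and height must be positive")
    if x0 < 0 or y0 < 0 or x0 + w > shape[1] or y0 + h > shape[0]:
        raise ROIError(f"rectangle {rect} exceeds image shape {shape}")
    mask = np.zeros(shape, dtype=bool)
    mask[y0 : y0 + h, x0 : x0 + w] = True
    return mask


def linearize(frame: BayerFrame) -> LinearMosaic:
    """Subtract the black level and flag saturated photosites.

    Output values are max(0, DN − black_level); pixels at or above the white
    level are flagged rather than dropped so downstream statistics can decide
    how to treat them.
    """
    values = np.maximum(np.asarray(frame.dn, dtype=float) - frame.black_level, 0.0)
    saturated = np.asarray(frame.dn) >= frame.white_level
    return LinearMosaic(
        values=values,
        saturation_mask=saturated,
        cfa_pattern=frame.cfa_pattern,
        exposure_time=frame.exposure_time,
        iso_scale=frame.iso_scale,
        device_id=frame.device_id,
        flash_on=frame.flash_on,
    )


_KERNEL_G = np.array([[0.0, 1.0, 0.0], [1.0, 4.0, 1.0], [0.0, 1.0, 0.0]])
_KERNEL_RB = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]])


def demosaic(mosaic: LinearMosaic, cfa_pattern: str | None = None) -> RGBImage:
    """Bilinear demosaic by normalized convolution.

    At photosites where a channel is sampled the sampled value passes through
    unchanged; elsewhere it is the bilinear average of the nearest samples of
    that channel. Edges fall back to the mean of the available neighbours,
    which keeps flat fields exactly flat everywhere.
    """
    pattern = cfa_pattern or mosaic.cfa_pattern
    chan_map = cfa_channel_map(mosaic.shape, pattern)
    planes = []
    for ch, kernel in ((0, _KERNEL_RB), (1, _KERNEL_G), (2, _KERNEL_RB)):
        sampled = (chan_map == ch).astype(float)
        num = ndimage.convolve(mosaic.values * sampled, kernel, mode="constant")
        den = ndimage.convolve(sampled, kernel, mode="constant")
        planes.append(num / den)
    # A saturated photosite contaminates every interpolated value it feeds.
    sat = ndimage.binary_dilation(mosaic.saturation_mask, np.ones((3, 3), bool))
    return RGBImage(r=planes[0], g=planes[1], b=planes[2], saturation_mask=sat)


def _roi_reduce(img: RGBImage, roi: np.ndarray, reducer, exclude_saturated: bool):
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise ROIError(f"ROI shape {roi.shape} does not match image {img.shape}")
    if not roi.any():
        raise ROIError("ROI mask selects no pixels")
    use = roi
    if exclude_saturated and img.saturation_mask is not None:
        frac = float((roi & img.saturation_mask).sum()) / float(roi.sum())
        if frac > SATURATION_ERROR_FRACTION:
            raise SaturationError(
                f"{frac:.1%} of ROI pixels saturated (limit "
                f"{SATURATION_ERROR_FRACTION:.0%}); retake at lower exposure"
            )
        if frac > SATURATION_WARN_FRACTION:
            warnings.warn(
                f"{frac:.1%} of ROI pixels saturated; statistics may be biased",
                stacklevel=3,
            )
        use = roi & ~img.saturation_mask
        if not use.any():
            raise SaturationError("every ROI pixel is saturated")
    return np.array([reducer(plane[use]) for plane in (img.r, img.g, img.b)])


def roi_median_rgb(
    img: RGBImage, roi: np.ndarray, exclude_saturated: bool = True
) -> np.ndarray:
    """Per-channel median over the ROI; the robust statistic used for color."""
    return _roi_reduce(img, roi, np.median, exclude_saturated)


def roi_mean_rgb(
    img: RGBImage, roi: np.ndarray, exclude_saturated: bool = True
) -> np.ndarray:
    """Per-channel mean over the ROI; used for the SSNR signal estimate."""
    return _roi_reduce(img, roi, np.mean, exclude_saturated)


# ---------------------------------------------------------------------------
# Fixture and layout I/O

_SIDECAR_FIELDS = (
    "cfa_pattern",
    "black_level",
    "white_level",
    "exposure_time_s",
    "iso_scale",
    "flash_on",
    "device_id",
    "seed",
)


def write_fixture(frame: BayerFrame, image_path, sidecar_path) -> None:
    """Write a frame as a 16-bit single-channel TIFF plus a JSON sidecar."""
    import tifffile

    dn = np.asarray(frame.dn)
    if not np.issubdtype(dn.dtype, np.integer):
        dn = np.rint(dn)  # noiseless float frames quantize only at export
    if dn.max() > np.iinfo(np.uint16).max:
        raise MetadataError("DN exceeds 16-bit range; cannot write fixture")
    tifffile.imwrite(str(image_path), dn.astype(np.uint16))
    sidecar = {
        "cfa_pattern": frame.cfa_pattern,
        "black_level": frame.black_level,
        "white_level": frame.white_level,
        "exposure_time_s": frame.exposure_time,
        "iso_scale": frame.iso_scale,
        "flash_on": frame.flash_on,
        "device_id": frame.device_id,
        "seed": frame.seed,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_fixture(image_path, sidecar_path) -> BayerFrame:
    """Read a TIFF + JSON sidecar fixture back into a :class:`BayerFrame`."""
    import tifffile

    meta = json.loads(Path(sidecar_path).read_text())
    for fld in _SIDECAR_FIELDS:
        if fld not in meta:
            raise MetadataError(f"sidecar {sidecar_path} missing field {fld!r}")
    dn = tifffile.imread(str(image_path))
    return BayerFrame(
        dn=dn,
        cfa_pattern=meta["cfa_pattern"],
        black_level=meta["black_level"],
        white_level=meta["white_level"],
        exposure_time=meta["exposure_time_s"],
        iso_scale=meta["iso_scale"],
        flash_on=meta["flash_on"],
        device_id=meta["device_id"],
        seed=meta["seed"],
    )


def read_raw_container(path) -> BayerFrame:
    """Read a camera raw container (e.g. DNG) into a :class:`BayerFrame`.

    Requires the optional ``rawpy`` dependency (``pip install chromacal[dng]``).
    Exposure time and ISO are not stored in rawpy's decode; they must be in an
    adjacent ``<path>.json`` sidecar with ``exposure_time_s`` and ``iso_scale``.
    """
    try:
        import rawpy
    except ImportError as exc:
        raise ChromacalError(
            "reading raw containers requires the optional 'rawpy' dependency"
        ) from exc

    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise MetadataError(f"sidecar {sidecar_path} missing field 'exposure_time_s'")
    meta = json.loads(sidecar_path.read_text())
    for fld in ("exposure_time_s", "iso_scale"):
        if fld not in meta:
            raise MetadataError(f"sidecar {sidecar_path} missing field {fld!r}")
    with rawpy.imread(str(path)) as raw:
        desc = raw.color_desc.decode()
        order = "".join(desc[i] for i in raw.raw_pattern.flatten())
        pattern = order.replace("G2", "G")
        if pattern not in CFA_PATTERNS:
            raise PatternError(f"unsupported CFA pattern {pattern!r} in {path}")
        return BayerFrame(
            dn=np.asarray(raw.raw_image_visible).copy(),
            cfa_pattern=pattern,
            black_level=float(np.mean(raw.black_level_per_channel)),
            white_level=float(raw.white_level),
            exposure_time=meta["exposure_time_s"],
            iso_scale=meta["iso_scale"],
            flash_on=bool(meta.get("flash_on", False)),
            device_id=str(meta.get("device_id", "")),
        )


def load_roi_layout(path) -> dict[str, tuple[int, int, int, int]]:
    """Load a patch-ROI layout: JSON mapping patch_id → [x0, y0, w, h]."""
    raw = json.loads(Path(path).read_text())
    layout = {}
    for pid, rect in raw.items():
        if len(rect) != 4:
            raise MetadataError(f"ROI for patch {pid!r} must be [x0, y0, w, h]")
        layout[pid] = tuple(int(v) for v in rect)
    return layout


def save_roi_layout(layout: dict, path) -> None:
    serial = {pid: list(rect) for pid, rect in layout.items()}
    Path(path).write_text(json.dumps(serial, indent=1, sort_keys=True))
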