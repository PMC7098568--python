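"""One-time per-device colorimetric calibration.

A new device is characterized once by imaging two flash/no-flash pairs with
minimal ambient light: a colorcard of patches with known XYZ values, and a
neutral grey card. The grey card's green channel measures the spatial
intensity profile of the flash across the card; dividing each colorcard
patch by the corresponding grey intensity is the Intensity Non-Uniformity
Correction (INUC). The corrected native RGB rows R (N×3) and reference XYZ
rows H (N×3) then determine a 3×3 device-specific mapping M minimizing
‖RM − H‖_F — the classic linear least-squares camera characterization
M = (RᵀR)⁻¹RᵀH, solved here by orthogonal decomposition for conditioning.

Because measurements are ambient-subtracted before mapping, the flash is the
only effective illuminant ever seen, so one calibration per device suffices.
The linear (as opposed to polynomial) form keeps the mapping exposure-time
independent: scaling all of R scales XYZ uniformly and chromaticity is
unchanged.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ambient import DEFAULT_SSNR_THRESHOLD, quality_gate, subtract_pair
from .errors import (
    AlignmentError,
    ChromacalError,
    ConditioningError,
    IntensityError,
    QualityGateError,
)
from .frames import BayerFrame, RGBImage, demosaic, linearize, rect_mask, roi_median_rgb
from .spectra import Reflectance

__all__ = [
    "ReferenceCard",
    "PatchMatrix",
    "IntensityMap",
    "ColorMapping",
    "grey_intensity",
    "inuc_correct",
    "fit_linear_mapping",
    "apply_mapping",
    "calibrate_device",
    "save_mapping",
    "load_mapping",
]


@dataclass(frozen=True)
class ReferenceCard:
    """Known reference XYZ per patch (CIE D50-referenced), optionally with spectra.

    The XYZ table is what a card manufacturer provides or a spectrophotometer
    measures; the optional reflectance spectra exist only so the simulator
    can render the same card.
    """

    name: str
    xyz: dict[str, np.ndarray]
    spectra: dict[str, Reflectance] | None = None

    def __post_init__(self) -> None:
        if len(self.xyz) < 3:
            raise ChromacalError("a reference card needs at least 3 patches")
        clean = {}
        for pid, triplet in self.xyz.items():
            arr = np.asarray(triplet, dtype=float)
            if arr.shape != (3,) or np.any(arr < 0):
                raise ChromacalError(f"invalid XYZ for patch {pid!r}")
            clean[pid] = arr
        object.__setattr__(self, "xyz", clean)

    @property
    def patch_ids(self) -> tuple[str, ...]:
        return tuple(self.xyz.keys())

    def xyz_matrix(self, patch_ids=None) -> "PatchMatrix":
        ids = tuple(patch_ids) if patch_ids is not None else self.patch_ids
        return PatchMatrix(ids, np.array([self.xyz[p] for p in ids]))

    def to_json(self, path) -> None:
        payload = {"name": self.name, "patches": {p: list(v) for p, v in self.xyz.items()}}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "ReferenceCard":
        raw = json.loads(Path(path).read_text())
        return cls(name=raw["name"], xyz={p: np.array(v) for p, v in raw["patches"].items()})

    @classmethod
    def from_csv(cls, path, name: str | None = None) -> "ReferenceCard":
        """CSV with header patch_id,X,Y,Z."""
        xyz = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                xyz[row["patch_id"]] = np.array(
                    [float(row["X"]), float(row["Y"]), float(row["Z"])]
                )
        return cls(name=name or Path(path).stem, xyz=xyz)


@dataclass(frozen=True)
class PatchMatrix:
    """Ordered patch ids with an N×3 value matrix (native RGB or XYZ rows)."""

    patch_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape != (len(self.patch_ids), 3):
            raise AlignmentError("value matrix must be N×3 aligned with patch ids")
        if len(set(self.patch_ids)) != len(self.patch_ids):
            raise AlignmentError("patch ids must be unique")
        if len(self.patch_ids) < 3:
            raise AlignmentError("need at least 3 patches")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "patch_ids", tuple(self.patch_ids))


@dataclass(frozen=True)
class IntensityMap:
    """Per-patch grey-card intensity, normalized to unit mean.

    ``global_level`` keeps the normalizing constant (the raw mean green
    level) so calibration can also remove the overall intensity scale, making
    the fitted mapping independent of the calibration exposure time.
    """

    values: dict[str, float]
    global_level: float = 1.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.values.values()):
            raise IntensityError("intensity values must be positive")
        mean = float(np.mean(list(self.values.values())))
        if abs(mean - 1.0) > 1e-12:
            raise IntensityError("intensity map must be normalized to unit mean")


@dataclass(frozen=True)
class ColorMapping:
    """Device-specific 3×3 matrix M mapping native RGB rows to XYZ rows."""

    matrix: np.ndarray
    device_id: str = ""
    card_name: str = ""
    residuals: dict[str, float] = field(default_factory=dict)
    condition_number: float = float("nan")

    def __post_init__(self) -> None:
        arr = np.asarray(self.matrix, dtype=float)
        if arr.shape != (3, 3) or not np.all(np.isfinite(arr)):
            raise ConditioningError("mapping must be a finite 3×3 matrix")
        object.__setattr__(self, "matrix", arr)


def grey_intensity(grey_rgb_image: RGBImage, rois: dict) -> IntensityMap:
    """Per-patch flash intensity from the grey card's green channel.

    The input is the subtracted (flash-only) demosaiced grey-card image; the
    green channel serves as the indicator of overall illumination intensity.
    Patch means are normalized to unit mean.
    """
    raw = {}
    for pid, rect in rois.items():
        mask = rect_mask(grey_rgb_image.shape, tuple(rect))
        level = float(grey_rgb_image.g[mask].mean())
        if level <= 0:
            raise IntensityError(f"grey green mean for patch {pid!r} is non-positive")
        raw[pid] = level
    global_level = float(np.mean(list(raw.values())))
    return IntensityMap(
        values={p: v / global_level for p, v in raw.items()},
        global_level=global_level,
    )


def inuc_correct(patch_rgb: PatchMatrix, intensity: IntensityMap) -> PatchMatrix:
    """Divide each patch's RGB row by that patch's grey intensity scalar."""
    if set(patch_rgb.patch_ids) != set(intensity.values):
        raise AlignmentError("patch ids of RGB matrix and intensity map differ")
    factors = np.array([intensity.values[p] for p in patch_rgb.patch_ids])
    return PatchMatrix(patch_rgb.patch_ids, patch_rgb.values / factors[:, None])


def fit_linear_mapping(
    R: PatchMatrix, H: PatchMatrix, device_id: str = "", card_name: str = ""
) -> ColorMapping:
    """Least-squares fit of M minimizing ‖RM − H‖_F over aligned patches.

    Solved via orthogonal decomposition (``lstsq``), equivalent to the normal
    equations (RᵀR)⁻¹RᵀH but numerically stable. Per-patch residual norms
    and the design condition number are reported with the mapping.
    """
    if R.patch_ids != H.patch_ids:
        raise AlignmentError("RGB and XYZ matrices must list identical patch ids")
    if np.linalg.matrix_rank(R.values) < 3:
        raise ConditioningError("RGB design matrix is rank deficient; cannot fit")
    matrix, *_ = np.linalg.lstsq(R.values, H.values, rcond=None)
    fitted = R.values @ matrix
    residuals = {
        pid: float(np.linalg.norm(fitted[i] - H.values[i]))
        for i, pid in enumerate(R.patch_ids)
    }
    return ColorMapping(
        matrix=matrix,
        device_id=device_id,
        card_name=card_name,
        residuals=residuals,
        condition_number=float(np.linalg.cond(R.values)),
    )


def apply_mapping(rgb, mapping: ColorMapping, clip_negative: bool = True) -> np.ndarray:
    """Map a native RGB triplet to XYZ: row vector times M.

    Out-of-gamut inputs can produce small negative tristimulus components;
    these are clipped to zero (with a warning) unless ``clip_negative`` is
    False.
    """
    rgb = np.asarray(rgb, dtype=float)
    xyz = rgb @ mapping.matrix
    if clip_negative and np.any(xyz < 0):
        warnings.warn("negative mapped tristimulus clipped to 0", stacklevel=2)
        xyz = np.maximum(xyz, 0.0)
    return xyz


def calibrate_device(
    colorcard_pair: tuple[BayerFrame, BayerFrame],
    greycard_pair: tuple[BayerFrame, BayerFrame],
    rois: dict,
    card: ReferenceCard,
    ssnr_threshold: float = DEFAULT_SSNR_THRESHOLD,
) -> ColorMapping:
    """Run the full one-time calibration from two flash/no-flash pairs.

    Pipeline: SSNR-gate both pairs → linearize and demosaic → per-patch
    median subtraction on the colorcard → pixelwise-subtracted grey image →
    grey-card INUC (including removal of the global intensity level, which
    makes the result independent of the calibration exposure time) → linear
    least-squares fit against the card's reference XYZ.
    """
    missing = [p for p in rois if p not in card.xyz]
    if missing:
        raise AlignmentError(f"ROIs name patches absent from card: {missing}")

    cc_flash, cc_noflash = colorcard_pair
    gc_flash, gc_noflash = greycard_pair
    union = np.zeros(cc_flash.shape, dtype=bool)
    for rect in rois.values():
        union |= rect_mask(cc_flash.shape, tuple(rect))
    for label, (fl, nf), roi in (
        ("colorcard", colorcard_pair, union),
        ("greycard", greycard_pair, np.ones(gc_flash.shape, dtype=bool)),
    ):
        report = quality_gate(fl, nf, roi, threshold=ssnr_threshold)
        if not report.passed:
            raise QualityGateError(
                f"{label} pair SSNR {report.ssnr:.2f} below threshold "
                f"{ssnr_threshold}; suggest retaking the images"
            )

    img_flash = demosaic(linearize(cc_flash))
    img_noflash = demosaic(linearize(cc_noflash))
    ids = tuple(rois.keys())
    rows = []
    for pid in ids:
        mask = rect_mask(img_flash.shape, tuple(rois[pid]))
        med_f = roi_median_rgb(img_flash, mask)
        med_a = roi_median_rgb(img_noflash, mask)
        try:
            rows.append(subtract_pair(med_f, med_a))
        except ChromacalError as exc:
            raise type(exc)(f"patch {pid!r}: {exc}") from exc
    R = PatchMatrix(ids, np.array(rows))

    # Grey card is static between frames, so pixelwise subtraction is safe here.
    grey_f = demosaic(linearize(gc_flash))
    grey_a = demosaic(linearize(gc_noflash))
    grey_only = RGBImage(
        r=grey_f.r - grey_a.r,
        g=grey_f.g - grey_a.g,
        b=grey_f.b - grey_a.b,
        saturation_mask=grey_f.saturation_mask,
    )
    grey_rois = _map_rois_to_grey(rois, img_flash.shape, grey_only.shape)
    intensity = grey_intensity(grey_only, grey_rois)
    corrected = inuc_correct(R, intensity)
    corrected = PatchMatrix(ids, corrected.values / intensity.global_level)

    H = card.xyz_matrix(ids)
    return fit_linear_mapping(
        corrected, H, device_id=cc_flash.device_id, card_name=card.name
    )


def _map_rois_to_grey(rois: dict, card_shape, grey_shape) -> dict:
    """Patch ROIs transferred onto the grey-card frame.

    The protocol keeps the phone static between the colorcard and grey-card
    captures, so identical pixel rectangles sample identical flash-intensity
    regions. Shapes must agree for the transfer to be meaningful.
    """
    if card_shape != grey_shape:
        raise AlignmentError(
            f"grey frame shape {grey_shape} differs from colorcard {card_shape}; "
            "captures must share the camera geometry"
        )
    return dict(rois)


def save_mapping(mapping: ColorMapping, path) -> None:
    payload = {
        "device_id": mapping.device_id,
        "matrix": [float(v) for v in mapping.matrix.flatten()],
        "card": mapping.card_name,
        "residuals": mapping.residuals,
        "condition_number": mapping.condition_number,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_mapping(path) -> ColorMapping:
    raw = json.loads(Path(path).read_text())
    return ColorMapping(
        matrix=np.array(raw["matrix"]).reshape(3, 3),
        device_id=raw.get("device_id", ""),
        card_name=raw.get("card", ""),
        residuals=raw.get("residuals", {}),
        condition_number=raw.get("condition_number", float("nan")),
    )
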