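"""Physics-based Bayer sensor simulator.

Image formation follows the standard spectral model: the noiseless response
of channel c at pixel x is

    f_c(x) = m(x) · Σ_λ s(λ, x) · e(λ) · ρ_c(λ) · Δλ

with m a geometric shading factor, s the surface reflectance, e the scene
illumination and ρ_c the channel sensitivity. Flash and ambient sources add
at the photon level, so the expected flash+ambient response is exactly the
sum of the individual expectations — the property ambient subtraction rests
on. Sensor noise is shot noise only: realized photo-electron counts are
Poisson with the expectation above scaled by exposure time, ISO and gain.

Stochastic captures quantize to integer DN; deterministic captures (noise
off) return the unquantized expectation as float DN so that closed-form
tests are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LayoutError
from .frames import BayerFrame, cfa_channel_map
from .spectra import (
    DEFAULT_GRID,
    CameraSensitivity,
    IlluminantSPD,
    Reflectance,
    SpectrumGrid,
)

__all__ = [
    "ScenePatch",
    "SceneModel",
    "CameraModel",
    "CaptureSettings",
    "ideal_channel_response",
    "xyz_ground_truth",
    "render_frame",
    "render_pair",
    "make_card_scene",
    "make_grey_scene",
    "radial_falloff_field",
    "auto_exposure_time",
]


def ideal_channel_response(
    refl: Reflectance,
    illum: IlluminantSPD,
    sens: CameraSensitivity,
    shading: float = 1.0,
) -> np.ndarray:
    """Noiseless RGB response m · Σ_λ s(λ) e(λ) ρ_c(λ) Δλ for one surface.

    Rectangle-rule quadrature on the shared uniform grid; all inputs must be
    defined on the same :class:`~chromacal.spectra.SpectrumGrid`.
    """
    refl.grid.require_match(illum.grid)
    refl.grid.require_match(sens.grid)
    if not 0.0 < shading <= 1.0:
        raise ValueError("shading factor must lie in (0, 1]")
    spectrum = refl.values * illum.values
    return shading * refl.grid.step_nm * (sens.as_matrix() @ spectrum)


def xyz_ground_truth(
    refl: Reflectance, illum: IlluminantSPD, cmf: CameraSensitivity
) -> np.ndarray:
    """Reference XYZ tristimulus of a surface under an illuminant.

    Computed with the CIE standard observer packed as a camera sensitivity,
    and normalized so a perfect (unit) reflector has Y = 1 — the role the
    spectrophotometer plays for a physical colorcard.
    """
    raw = ideal_channel_response(refl, illum, cmf)
    y_white = refl.grid.step_nm * float(cmf.g @ illum.values)
    return raw / y_white


@dataclass(frozen=True)
class ScenePatch:
    """One card patch: a reflectance over a (x0, y0, w, h) pixel rectangle."""

    patch_id: str
    reflectance: Reflectance
    rect: tuple[int, int, int, int]


@dataclass(frozen=True)
class SceneModel:
    """Patch grid plus a per-pixel multiplicative shading field m(x) ∈ (0, 1]."""

    patches: tuple[ScenePatch, ...]
    shape: tuple[int, int]
    shading_field: np.ndarray

    def __post_init__(self) -> None:
        shading = np.asarray(self.shading_field, dtype=float)
        if shading.shape != self.shape:
            raise LayoutError("shading field shape must match scene shape")
        if np.any(shading <= 0) or np.any(shading > 1):
            raise LayoutError("shading factors must lie in (0, 1]")
        occupancy = np.zeros(self.shape, dtype=bool)
        for p in self.patches:
            x0, y0, w, h = p.rect
            if x0 < 0 or y0 < 0 or x0 + w > self.shape[1] or y0 + h > self.shape[0]:
                raise LayoutError(f"patch {p.patch_id!r} rect exceeds scene bounds")
            region = occupancy[y0 : y0 + h, x0 : x0 + w]
            if region.any():
                raise LayoutError(f"patch {p.patch_id!r} overlaps another patch")
            region[:] = True
        object.__setattr__(self, "shading_field", shading)
        object.__setattr__(self, "patches", tuple(self.patches))

    def patch_rois(self, margin: int = 0) -> dict[str, tuple[int, int, int, int]]:
        """ROI rectangles per patch, optionally inset to avoid demosaic bleed."""
        rois = {}
        for p in self.patches:
            x0, y0, w, h = p.rect
            if 2 * margin >= w or 2 * margin >= h:
                raise LayoutError(f"margin {margin} leaves no ROI for {p.patch_id!r}")
            rois[p.patch_id] = (x0 + margin, y0 + margin, w - 2 * margin, h - 2 * margin)
        return rois

    def patch_shading(self, patch_id: str) -> float:
        """Mean shading factor over a patch extent."""
        for p in self.patches:
            if p.patch_id == patch_id:
                x0, y0, w, h = p.rect
                return float(self.shading_field[y0 : y0 + h, x0 : x0 + w].mean())
        raise LayoutError(f"no patch {patch_id!r} in scene")


@dataclass(frozen=True)
class CameraModel:
    """A simulated device: spectral sensitivities, sensor scale, flash spectrum."""

    sensitivity: CameraSensitivity
    flash_spd: IlluminantSPD
    cfa_pattern: str = "RGGB"
    black_level: float = 64.0
    white_level: float = 4095.0
    gain: float = 1.0  # electrons per DN
    device_id: str = "sim-camera"

    def __post_init__(self) -> None:
        if not 0 <= self.black_level < self.white_level:
            raise ValueError("require 0 <= black_level < white_level")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        self.sensitivity.grid.require_match(self.flash_spd.grid)


@dataclass(frozen=True)
class CaptureSettings:
    """Exposure parameters for one capture (shared across a flash/no-flash pair)."""

    exposure_time: float
    iso_scale: float = 1.0
    flash_on: bool = False
    seed: int | None = None
    noise: bool = True

    def __post_init__(self) -> None:
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        if self.iso_scale <= 0:
            raise ValueError("iso_scale must be positive")


def _expected_electron_map(
    scene: SceneModel,
    camera: CameraModel,
    settings: CaptureSettings,
    illum: IlluminantSPD | None,
) -> np.ndarray:
    """Per-pixel expected photo-electron count at the pixel's CFA channel."""
    expected = np.zeros(scene.shape, dtype=float)
    if illum is None:
        return expected
    chan_map = cfa_channel_map(scene.shape, camera.cfa_pattern)
    scale = settings.exposure_time * settings.iso_scale * camera.gain
    for p in scene.patches:
        resp = ideal_channel_response(p.reflectance, illum, camera.sensitivity)
        x0, y0, w, h = p.rect
        sub_chan = chan_map[y0 : y0 + h, x0 : x0 + w]
        sub_shade = scene.shading_field[y0 : y0 + h, x0 : x0 + w]
        expected[y0 : y0 + h, x0 : x0 + w] = resp[sub_chan] * sub_shade * scale
    return expected


def _combine_illuminants(
    ambient: IlluminantSPD | None, flash: IlluminantSPD | None
) -> IlluminantSPD | None:
    if ambient is None:
        return flash
    if flash is None:
        return ambient
    ambient.grid.require_match(flash.grid)
    return IlluminantSPD(
        ambient.values + flash.values,
        name=f"{ambient.name}+{flash.name}",
        grid=ambient.grid,
    )


def render_frame(
    scene: SceneModel,
    camera: CameraModel,
    settings: CaptureSettings,
    ambient: IlluminantSPD | None = None,
    rng: np.random.Generator | None = None,
) -> BayerFrame:
    """Render one Bayer mosaic capture of the scene.

    The effective illuminant is the ambient source plus, when the flash flag
    is set, the camera's flash spectrum — additive at the photon level. In
    stochastic mode electron counts are Poisson draws and DN is
    round(count / gain) + black level, clipped to the sensor range; in
    deterministic mode the unquantized expectation is returned. Saturation is
    recorded via clipping, never raised.
    """
    illum = _combine_illuminants(ambient, camera.flash_spd if settings.flash_on else None)
    expected = _expected_electron_map(scene, camera, settings, illum)
    if settings.noise:
        if rng is None:
            rng = np.random.default_rng(settings.seed)
        counts = rng.poisson(expected).astype(float)
        dn = np.rint(counts / camera.gain) + camera.black_level
    else:
        dn = expected / camera.gain + camera.black_level
    dn = np.clip(dn, 0.0, camera.white_level)
    if settings.noise:
        dn = dn.astype(np.int64)
    return BayerFrame(
        dn=dn,
        cfa_pattern=camera.cfa_pattern,
        black_level=camera.black_level,
        white_level=camera.white_level,
        exposure_time=settings.exposure_time,
        iso_scale=settings.iso_scale,
        device_id=camera.device_id,
        flash_on=settings.flash_on,
        seed=settings.seed,
    )


def render_pair(
    scene: SceneModel,
    camera: CameraModel,
    settings: CaptureSettings,
    ambient: IlluminantSPD | None = None,
) -> tuple[BayerFrame, BayerFrame]:
    """Render a flash / no-flash pair at identical exposure time and ISO.

    The two frames differ only in the flash flag and in their (independent)
    shot-noise draws, mirroring two captures taken in quick succession under
    constant ambient light.
    """
    if settings.seed is not None:
        ss = np.random.SeedSequence(settings.seed)
        rng_flash, rng_ambient = (np.random.default_rng(s) for s in ss.spawn(2))
    else:
        rng_flash = rng_ambient = None
    flash = render_frame(
        scene,
        camera,
        CaptureSettings(
            settings.exposure_time, settings.iso_scale, True, settings.seed, settings.noise
        ),
        ambient,
        rng=rng_flash,
    )
    noflash = render_frame(
        scene,
        camera,
        CaptureSettings(
            settings.exposure_time, settings.iso_scale, False, settings.seed, settings.noise
        ),
        ambient,
        rng=rng_ambient,
    )
    return flash, noflash


def radial_falloff_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Quadratic vignetting: 1 at the image centre, 1 − strength at the corners."""
    if not 0 <= strength < 1:
        raise ValueError("falloff strength must lie in [0, 1)")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return 1.0 - strength * r2 / r2.max()


def make_card_scene(
    spectra: dict[str, Reflectance],
    layout: tuple[int, int],
    shading_profile: str = "uniform",
    falloff_strength: float = 0.5,
    patch_px: int = 32,
) -> SceneModel:
    """Lay card patches on a rows × cols grid with a named shading profile.

    ``shading_profile`` is ``"uniform"`` or ``"radial"`` (quadratic falloff of
    the given strength), emulating the intensity non-uniformity of a phone
    flash across a card.
    """
    rows, cols = layout
    if len(spectra) > rows * cols:
        raise LayoutError(f"{len(spectra)} spectra do not fit a {rows}×{cols} card")
    shape = (rows * patch_px, cols * patch_px)
    if shading_profile == "uniform":
        shading = np.ones(shape)
    elif shading_profile == "radial":
        shading = radial_falloff_field(shape, falloff_strength)
    else:
        raise LayoutError(f"unknown shading profile {shading_profile!r}")
    patches = []
    for k, (pid, refl) in enumerate(spectra.items()):
        r, c = divmod(k, cols)
        patches.append(
            ScenePatch(pid, refl, (c * patch_px, r * patch_px, patch_px, patch_px))
        )
    return SceneModel(patches=tuple(patches), shape=shape, shading_field=shading)


def make_grey_scene(
    reflectance_value: float = 0.35,
    shape: tuple[int, int] = (128, 192),
    shading_profile: str = "uniform",
    falloff_strength: float = 0.5,
    grid: SpectrumGrid = DEFAULT_GRID,
) -> SceneModel:
    """Single flat spectrally-neutral patch filling the frame (a grey card)."""
    refl = Reflectance(np.full(grid.n_bins, reflectance_value), grid=grid)
    if shading_profile == "uniform":
        shading = np.ones(shape)
    elif shading_profile == "radial":
        shading = radial_falloff_field(shape, falloff_strength)
    else:
        raise LayoutError(f"unknown shading profile {shading_profile!r}")
    patch = ScenePatch("grey", refl, (0, 0, shape[1], shape[0]))
    return SceneModel(patches=(patch,), shape=shape, shading_field=shading)


def auto_exposure_time(
    scene: SceneModel,
    camera: CameraModel,
    ambient: IlluminantSPD | None = None,
    flash_on: bool = True,
    target_fraction: float = 0.5,
    iso_scale: float = 1.0,
) -> float:
    """Exposure time putting the brightest noiseless patch at a target DN level.

    Mimics auto-exposure placing the signal in the sensor mid-range, where
    the linearity and shot-noise assumptions hold.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    probe = CaptureSettings(1.0, iso_scale, flash_on, None, False)
    illum = _combine_illuminants(ambient, camera.flash_spd if flash_on else None)
    expected = _expected_electron_map(scene, camera, probe, illum)
    peak_dn = expected.max() / camera.gain
    if peak_dn <= 0:
        raise ValueError("scene is dark; cannot auto-expose")
    return target_fraction * (camera.white_level - camera.black_level) / peak_dn
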