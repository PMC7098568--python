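"""Load camera and scene definitions from YAML study configs.

A study config is a plain-text key-value file with two optional top-level
sections, ``camera`` and ``scene``. Spectral curves may be given either as
explicit per-bin arrays on the default grid or as named presets of the
bundled standards::

    camera:
      device_id: phoneA
      cfa_pattern: RGGB
      black_level: 64
      white_level: 4095
      gain: 1.0
      sensitivity: {preset: gaussian, centers: [600, 540, 460], widths: [55, 50, 42]}
      flash: {preset: led}
    scene:
      card: classic24          # or {random: {n: 24, seed: 7}}
      layout: [4, 6]
      patch_px: 32
      shading: {profile: radial, strength: 0.3}
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .cards import classic24_reflectances, random_reflectances
from .errors import MetadataError
from .simulate import CameraModel, SceneModel, make_card_scene
from .spectra import DEFAULT_GRID, CameraSensitivity, IlluminantSPD
from .standards import (
    d50_flash,
    daylight_ambient,
    fluorescent_ambient,
    gaussian_camera_sensitivity,
    led_flash,
    luther_camera_sensitivity,
    screen_flash,
)

__all__ = ["load_config", "camera_from_config", "scene_from_config"]

_FLASH_PRESETS = {
    "led": led_flash,
    "screen": screen_flash,
    "d50": d50_flash,
    "daylight": daylight_ambient,
    "fluorescent": fluorescent_ambient,
}


def _sensitivity_from(spec: dict) -> CameraSensitivity:
    preset = spec.get("preset")
    if preset == "gaussian":
        kwargs = {}
        if "centers" in spec:
            kwargs["centers_nm"] = tuple(float(v) for v in spec["centers"])
        if "widths" in spec:
            kwargs["widths_nm"] = tuple(float(v) for v in spec["widths"])
        return gaussian_camera_sensitivity(**kwargs)
    if preset == "luther":
        return luther_camera_sensitivity()
    if all(ch in spec for ch in "rgb"):
        return CameraSensitivity(
            r=np.asarray(spec["r"], float),
            g=np.asarray(spec["g"], float),
            b=np.asarray(spec["b"], float),
            grid=DEFAULT_GRID,
        )
    raise MetadataError(f"cannot build sensitivity from {spec!r}")


def _flash_from(spec: dict) -> IlluminantSPD:
    preset = spec.get("preset")
    if preset is not None:
        if preset not in _FLASH_PRESETS:
            raise MetadataError(f"unknown illuminant preset {preset!r}")
        spd = _FLASH_PRESETS[preset]()
    elif "values" in spec:
        spd = IlluminantSPD(
            np.asarray(spec["values"], float),
            name=str(spec.get("name", "")),
            grid=DEFAULT_GRID,
        )
    else:
        raise MetadataError(f"cannot build illuminant from {spec!r}")
    scale = spec.get("scale")
    return spd if scale is None else spd.scaled(float(scale))


def camera_from_config(cfg: dict) -> CameraModel:
    try:
        sens = _sensitivity_from(cfg["sensitivity"])
        flash = _flash_from(cfg["flash"])
    except KeyError as exc:
        raise MetadataError(f"camera config missing field {exc.args[0]!r}") from exc
    return CameraModel(
        sensitivity=sens,
        flash_spd=flash,
        cfa_pattern=cfg.get("cfa_pattern", "RGGB"),
        black_level=float(cfg.get("black_level", 64.0)),
        white_level=float(cfg.get("white_level", 4095.0)),
        gain=float(cfg.get("gain", 1.0)),
        device_id=str(cfg.get("device_id", "sim-camera")),
    )


def scene_from_config(cfg: dict) -> SceneModel:
    card = cfg.get("card", "classic24")
    if card == "classic24":
        bank = classic24_reflectances()
    elif isinstance(card, dict) and "random" in card:
        spec = card["random"]
        bank = random_reflectances(int(spec["n"]), seed=int(spec.get("seed", 0)))
    else:
        raise MetadataError(f"unknown card spec {card!r}")
    layout = tuple(int(v) for v in cfg.get("layout", (4, 6)))
    shading = cfg.get("shading", {"profile": "uniform"})
    return make_card_scene(
        bank,
        layout,
        shading_profile=str(shading.get("profile", "uniform")),
        falloff_strength=float(shading.get("strength", 0.5)),
        patch_px=int(cfg.get("patch_px", 32)),
    )


def load_config(path) -> dict:
    """Load a study config; returns {'camera': CameraModel?, 'scene': SceneModel?}."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out = {}
    if "camera" in raw:
        out["camera"] = camera_from_config(raw["camera"])
    if "scene" in raw:
        out["scene"] = scene_from_config(raw["scene"])
    return out
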