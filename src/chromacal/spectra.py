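"""Spectral containers on a shared uniform wavelength grid.

All spectral quantities in a computation — surface reflectance s(λ), scene
illumination e(λ) and camera channel sensitivities ρ^c(λ) — live on one
uniform grid over the visible range (default 380–730 nm in 10 nm steps).
Integrals are rectangle-rule sums, value · Δλ, which is adequate for the
smooth curves used here and trivially matched by an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError

__all__ = [
    "SpectrumGrid",
    "Reflectance",
    "IlluminantSPD",
    "CameraSensitivity",
    "DEFAULT_GRID",
]


@dataclass(frozen=True)
class SpectrumGrid:
    """Uniform wavelength grid [start_nm, stop_nm] inclusive, step_nm spacing."""

    start_nm: float = 380.0
    stop_nm: float = 730.0
    step_nm: float = 10.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.stop_nm:
            raise ValueError("grid start must be below stop")
        if self.step_nm <= 0:
            raise ValueError("grid step must be positive")
        span = self.stop_nm - self.start_nm
        n, rem = divmod(span, self.step_nm)
        if abs(rem) > 1e-9 and abs(rem - self.step_nm) > 1e-9:
            raise ValueError("grid span must be divisible by step")

    @property
    def n_bins(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bins)

    def require_match(self, other: "SpectrumGrid") -> None:
        if self != other:
            raise GridMismatchError(f"grids differ: {self} vs {other}")


DEFAULT_GRID = SpectrumGrid()


def _as_grid_array(values, grid: SpectrumGrid, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (grid.n_bins,):
        raise GridMismatchError(
            f"{name} has {arr.shape} values for a grid of {grid.n_bins} bins"
        )
    return arr


@dataclass(frozen=True)
class Reflectance:
    """Spectral reflectance s(λ) of a surface; unitless, in [0, 1]."""

    values: np.ndarray
    grid: SpectrumGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        arr = _as_grid_array(self.values, self.grid, "reflectance")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("reflectance values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class IlluminantSPD:
    """Relative spectral power distribution e(λ) of a light source."""

    values: np.ndarray
    name: str = ""
    grid: SpectrumGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        arr = _as_grid_array(self.values, self.grid, f"illuminant {self.name!r}")
        if np.any(arr < 0):
            raise ValueError("illuminant power must be non-negative")
        if not np.any(arr > 0):
            raise ValueError("illuminant must not be identically zero")
        object.__setattr__(self, "values", arr)

    def scaled(self, factor: float) -> "IlluminantSPD":
        """Same spectral shape at `factor` times the power (factor > 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return IlluminantSPD(self.values * factor, name=self.name, grid=self.grid)


@dataclass(frozen=True)
class CameraSensitivity:
    """Per-channel spectral sensitivities ρ^c(λ), c ∈ {R, G, B}."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    grid: SpectrumGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        for ch in "rgb":
            arr = _as_grid_array(getattr(self, ch), self.grid, f"sensitivity {ch}")
            if np.any(arr < 0):
                raise ValueError(f"sensitivity {ch} must be non-negative")
            if not np.any(arr > 0):
                raise ValueError(f"sensitivity {ch} must have a positive value")
            object.__setattr__(self, ch, arr)

    def as_matrix(self) -> np.ndarray:
        """Stack channels as a (3, n_bins) array in R, G, B order."""
        return np.stack([self.r, self.g, self.b])
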