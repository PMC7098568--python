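"""Bundled colorimetric standards and synthetic device spectra.

The CSV tables under ``chromacal/data`` are the published CIE 1931 2° color
matching functions and the CIE D50 / D65 illuminant power distributions,
resampled on the package's default 380–730 nm / 10 nm grid. Everything else
here is synthetic by construction: flash spectra, fluorescent ambient, and
two families of phone sensitivities used as simulated devices. No claim is
made that these match any real handset; they provide the statistical
structure (smooth curves, distinct devices, a Luther-satisfying limit case)
that the pipeline tests require.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .spectra import DEFAULT_GRID, CameraSensitivity, IlluminantSPD, SpectrumGrid

__all__ = [
    "cie_cmf",
    "illuminant_d50",
    "daylight_ambient",
    "fluorescent_ambient",
    "led_flash",
    "screen_flash",
    "d50_flash",
    "gaussian_camera_sensitivity",
    "luther_camera_sensitivity",
]


def _load_table(name: str) -> np.ndarray:
    path = resources.files("chromacal.data").joinpath(name)
    with path.open("r") as fh:
        return np.loadtxt(fh, delimiter=",", skiprows=1)


def _check_grid(wavelengths: np.ndarray, grid: SpectrumGrid) -> None:
    if not np.allclose(wavelengths, grid.wavelengths):
        raise ValueError("bundled table wavelengths do not match requested grid")


def cie_cmf(grid: SpectrumGrid = DEFAULT_GRID) -> CameraSensitivity:
    """CIE 1931 2° color matching functions x̄, ȳ, z̄ packed as a sensitivity.

    Packing the standard observer into the camera-sensitivity container lets
    the same spectral integration path compute XYZ tristimulus ground truth.
    """
    tab = _load_table("cie_1931_2deg_10nm.csv")
    _check_grid(tab[:, 0], grid)
    return CameraSensitivity(r=tab[:, 1], g=tab[:, 2], b=tab[:, 3], grid=grid)


def illuminant_d50(grid: SpectrumGrid = DEFAULT_GRID) -> IlluminantSPD:
    """CIE D50 (~5000 K daylight), the XYZ reference illuminant used here."""
    tab = _load_table("illuminant_d50_10nm.csv")
    _check_grid(tab[:, 0], grid)
    return IlluminantSPD(tab[:, 1], name="D50", grid=grid)


def daylight_ambient(grid: SpectrumGrid = DEFAULT_GRID) -> IlluminantSPD:
    """Daylight-like ambient source (CIE D65 shape)."""
    tab = _load_table("illuminant_d65_10nm.csv")
    _check_grid(tab[:, 0], grid)
    return IlluminantSPD(tab[:, 1], name="daylight", grid=grid)


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def fluorescent_ambient(grid: SpectrumGrid = DEFAULT_GRID) -> IlluminantSPD:
    """Fluorescent-like ambient: narrow triband peaks on a weak continuum."""
    wl = grid.wavelengths
    spd = (
        0.06
        + 1.00 * _gaussian(wl, 435.0, 8.0)
        + 1.40 * _gaussian(wl, 545.0, 9.0)
        + 1.15 * _gaussian(wl, 611.0, 9.0)
        + 0.25 * _gaussian(wl, 487.0, 10.0)
    )
    return IlluminantSPD(100.0 * spd / spd.max(), name="fluorescent", grid=grid)


def led_flash(grid: SpectrumGrid = DEFAULT_GRID) -> IlluminantSPD:
    """White-LED-like flash: blue pump plus broad phosphor emission."""
    wl = grid.wavelengths
    spd = 1.0 * _gaussian(wl, 450.0, 12.0) + 0.85 * _gaussian(wl, 560.0, 60.0)
    return IlluminantSPD(100.0 * spd / spd.max(), name="led-flash", grid=grid)


def screen_flash(grid: SpectrumGrid = DEFAULT_GRID) -> IlluminantSPD:
    """Screen-backlight-like flash: three moderate-width emitter bands."""
    wl = grid.wavelengths
    spd = (
        0.95 * _gaussian(wl, 452.0, 16.0)
        + 1.00 * _gaussian(wl, 530.0, 28.0)
        + 0.90 * _gaussian(wl, 615.0, 24.0)
    )
    return IlluminantSPD(100.0 * spd / spd.max(), name="screen-flash", grid=grid)


def d50_flash(grid: SpectrumGrid = DEFAULT_GRID) -> IlluminantSPD:
    """Flash with the D50 spectral shape.

    Used with the Luther-limit fixture camera: an exact linear RGB→XYZ map
    exists only when the calibration illumination matches the illuminant the
    reference XYZ values assume.
    """
    d50 = illuminant_d50(grid)
    return IlluminantSPD(d50.values, name="d50-flash", grid=grid)


def gaussian_camera_sensitivity(
    centers_nm: tuple[float, float, float] = (600.0, 540.0, 460.0),
    widths_nm: tuple[float, float, float] = (55.0, 50.0, 42.0),
    grid: SpectrumGrid = DEFAULT_GRID,
) -> CameraSensitivity:
    """Synthetic phone sensitivity from one Gaussian band per channel.

    Gaussian bands are not linear combinations of the CIE observer, so these
    cameras violate the Luther condition — as real phone sensors do — and a
    3×3 mapping to XYZ can only ever be approximate for them.
    """
    wl = grid.wavelengths
    cr, cg, cb = centers_nm
    wr, wg, wb = widths_nm
    return CameraSensitivity(
        r=_gaussian(wl, cr, wr),
        g=_gaussian(wl, cg, wg),
        b=_gaussian(wl, cb, wb),
        grid=grid,
    )


#: Mixing matrix applied to (x̄, ȳ, z̄) rows for the Luther fixture camera.
#: Non-negative and invertible, so the sensitivities stay physical while an
#: exact 3×3 inverse back to XYZ exists.
_LUTHER_MIX = np.array(
    [
        [0.85, 0.10, 0.05],
        [0.05, 0.90, 0.05],
        [0.02, 0.08, 0.90],
    ]
)


def luther_camera_sensitivity(grid: SpectrumGrid = DEFAULT_GRID) -> CameraSensitivity:
    """Camera whose channels are linear combinations of the CIE observer.

    Satisfies the Luther condition: native RGB is an invertible linear image
    of XYZ tristimulus, so a 3×3 least-squares mapping can be exact (up to
    the illuminant caveat; see :func:`d50_flash`).
    """
    cmf = cie_cmf(grid).as_matrix()
    mixed = _LUTHER_MIX @ cmf
    return CameraSensitivity(r=mixed[0], g=mixed[1], b=mixed[2], grid=grid)
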