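"""Synthetic colorcards: smooth reflectance banks plus reference XYZ tables.

Physical card spectra are proprietary, and only their statistical structure
matters for exercising the pipeline, so every card here is generated from a
low-dimensional basis of smooth spectral primitives (band-pass bumps,
sigmoid cut-on/cut-off edges, notches). Three families are provided:

* a deterministic 24-patch general-purpose card (18 chromatic + 6 neutral
  patches spanning the hue circle), the stand-in for a classic colorcard;
* seeded random smooth reflectances, used as held-out "scene" patches;
* yellow-region cards (training and test drawn from different generator
  families) for the custom-card experiment, where a calibration focused on
  a narrow color range should beat the general card inside that range.

Reference XYZ values are computed from the spectra under CIE D50 with the
1931 2° observer, normalized so a perfect reflector has Y = 1 — the role a
spectrophotometer plays for a real card.
"""

from __future__ import annotations

import numpy as np

from .calibration import ReferenceCard
from .simulate import xyz_ground_truth
from .spectra import DEFAULT_GRID, Reflectance, SpectrumGrid
from .standards import cie_cmf, illuminant_d50

__all__ = [
    "classic24_reflectances",
    "random_reflectances",
    "yellow_training_reflectances",
    "yellow_test_reflectances",
    "neutral_reflectances",
    "reference_card_from_reflectances",
]


def _gauss(wl, center, width):
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(wl, edge, slope):
    return 1.0 / (1.0 + np.exp(-(wl - edge) / slope))


def _clip01(values):
    return np.clip(values, 0.0, 1.0)


def classic24_reflectances(grid: SpectrumGrid = DEFAULT_GRID) -> dict[str, Reflectance]:
    """Deterministic 24-patch general card: 18 chromatic + 6 neutral patches."""
    wl = grid.wavelengths
    chromatic = {
        "dark-skin": 0.06 + 0.30 * _sigmoid(wl, 580, 25),
        "light-skin": 0.15 + 0.45 * _sigmoid(wl, 560, 25),
        "blue-sky": 0.08 + 0.33 * _sigmoid(wl, 520, -25),
        "foliage": 0.05 + 0.22 * _gauss(wl, 545, 35),
        "blue-flower": 0.08 + 0.40 * _sigmoid(wl, 480, -28) + 0.25 * _sigmoid(wl, 640, 22),
        "bluish-green": 0.08 + 0.42 * _gauss(wl, 500, 45),
        "orange": 0.05 + 0.62 * _sigmoid(wl, 575, 16),
        "purplish-blue": 0.04 + 0.48 * _sigmoid(wl, 470, -24),
        "moderate-red": 0.06 + 0.52 * _sigmoid(wl, 600, 16),
        "purple": 0.35 * (1.0 - 0.85 * _gauss(wl, 550, 55)) + 0.02,
        "yellow-green": 0.06 + 0.52 * _gauss(wl, 560, 50),
        "orange-yellow": 0.05 + 0.58 * _sigmoid(wl, 545, 18),
        "blue": 0.03 + 0.45 * _sigmoid(wl, 455, -18),
        "green": 0.05 + 0.47 * _gauss(wl, 530, 32),
        "red": 0.04 + 0.60 * _sigmoid(wl, 620, 13),
        "yellow": 0.05 + 0.68 * _sigmoid(wl, 515, 16),
        "magenta": 0.55 * (1.0 - 0.90 * _gauss(wl, 540, 45)) + 0.04,
        "cyan": 0.06 + 0.42 * _sigmoid(wl, 540, -22),
    }
    bank = {pid: Reflectance(_clip01(vals), grid=grid) for pid, vals in chromatic.items()}
    bank.update(neutral_reflectances((0.90, 0.59, 0.36, 0.19, 0.09, 0.03), grid))
    return bank


def neutral_reflectances(levels, grid: SpectrumGrid = DEFAULT_GRID) -> dict[str, Reflectance]:
    """Spectrally flat grey patches at the given reflectance levels."""
    return {
        f"neutral-{level:.2f}": Reflectance(np.full(grid.n_bins, level), grid=grid)
        for level in levels
    }


def random_reflectances(
    n: int, seed: int, grid: SpectrumGrid = DEFAULT_GRID, prefix: str = "rand"
) -> dict[str, Reflectance]:
    """Seeded smooth random reflectances from a 3-bump Gaussian basis.

    A logistic squash keeps values inside [0.02, 0.95] without the hard
    clipping kinks that would be unphysical for real pigments.
    """
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    bank = {}
    for i in range(n):
        z = rng.normal(-0.3, 0.8)
        for _ in range(3):
            z = z + rng.normal(0, 1.6) * _gauss(
                wl, rng.uniform(400, 700), rng.uniform(30, 90)
            )
        squashed = 1.0 / (1.0 + np.exp(-z))
        bank[f"{prefix}-{i:03d}"] = Reflectance(0.02 + 0.93 * squashed, grid=grid)
    return bank


def yellow_training_reflectances(
    seed: int = 7, grid: SpectrumGrid = DEFAULT_GRID
) -> dict[str, Reflectance]:
    """Training yellows card: 24 cut-on yellows plus 6 neutrals (30 patches).

    Yellow surfaces absorb blue: reflectance rises through a sigmoid edge in
    the 470–530 nm region. Varying edge position, slope, amplitude and floor
    spans saturation and lightness within the yellow region.
    """
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    bank = {}
    for i in range(24):
        edge = rng.uniform(470, 530)
        slope = rng.uniform(12, 30)
        amp = rng.uniform(0.45, 0.85)
        base = rng.uniform(0.03, 0.10)
        bank[f"ytrain-{i:02d}"] = Reflectance(
            _clip01(base + amp * _sigmoid(wl, edge, slope)), grid=grid
        )
    bank.update(neutral_reflectances((0.85, 0.60, 0.40, 0.25, 0.12, 0.05), grid))
    return bank


def yellow_test_reflectances(
    seed: int = 11, grid: SpectrumGrid = DEFAULT_GRID
) -> dict[str, Reflectance]:
    """Test yellows card: 24 yellows from a different spectral family.

    Emulates a second manufacturer: the same blue-absorbing edge but with an
    added mid-green absorption dip and a mild red roll-off, so test spectra
    are metameric cousins of — not copies of — the training family.
    """
    rng = np.random.default_rng(seed)
    wl = grid.wavelengths
    bank = {}
    for i in range(24):
        edge = rng.uniform(475, 525)
        slope = rng.uniform(10, 25)
        amp = rng.uniform(0.45, 0.80)
        base = rng.uniform(0.03, 0.09)
        dip = rng.uniform(0.05, 0.18) * _gauss(wl, rng.uniform(540, 580), 25)
        roll = rng.uniform(0.0, 0.10) * _sigmoid(wl, 680, 15)
        vals = base + amp * _sigmoid(wl, edge, slope) - dip - roll
        bank[f"ytest-{i:02d}"] = Reflectance(_clip01(vals), grid=grid)
    return bank


def reference_card_from_reflectances(
    name: str,
    spectra: dict[str, Reflectance],
    grid: SpectrumGrid = DEFAULT_GRID,
) -> ReferenceCard:
    """Build a D50-referenced XYZ card table from reflectance spectra."""
    d50 = illuminant_d50(grid)
    cmf = cie_cmf(grid)
    xyz = {pid: xyz_ground_truth(refl, d50, cmf) for pid, refl in spectra.items()}
    return ReferenceCard(name=name, xyz=xyz, spectra=dict(spectra))
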