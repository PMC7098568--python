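"""Chromaticity algebra.

Chromaticity divides each channel by the channel sum, cancelling any global
scale factor — exposure level, distance, geometric shading — and reducing a
triplet to two coordinates: (x, y) from XYZ tristimulus, (r, g) from native
RGB. All device- and ambient-independent outputs of the pipeline are
chromaticities.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateColorError

__all__ = ["to_chromaticity", "to_xy", "to_rg", "rg_distance", "xy_distance"]


def to_chromaticity(triplet) -> tuple[float, float]:
    """First two normalized components of a triplet: (x, y) or (r, g).

    The third coordinate is redundant (the three sum to 1). Raises if the
    channel sum is not positive, since the color is then undefined.
    """
    arr = np.asarray(triplet, dtype=float)
    if arr.shape != (3,):
        raise DegenerateColorError("chromaticity needs a 3-component triplet")
    total = float(arr.sum())
    if total <= 0:
        raise DegenerateColorError(f"non-positive channel sum {total}")
    return float(arr[0] / total), float(arr[1] / total)


to_xy = to_chromaticity
to_rg = to_chromaticity


def rg_distance(test: tuple[float, float], gt: tuple[float, float]) -> float:
    """Euclidean distance between two rg (or xy) chromaticity points."""
    return math.hypot(test[0] - gt[0], test[1] - gt[1])


xy_distance = rg_distance
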