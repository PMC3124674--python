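"""Color filtering: segmenting stained cells from background.

A pixel belongs to the cell (in-range) region when the Euclidean distance
between its RGB triplet and the user-chosen base stain color is strictly
less than the margin of tolerance.  Distances are computed in raw 0-255 RGB
space; typical tolerances for strongly stained material are on the order of
100-135.  Grayscale targets are expressed as a base color ``(v, v, v)``
since grayscale images load with R = G = B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class ColorRange:
    """Base stain color plus a margin of tolerance.

    ``tolerance`` is a Euclidean radius in RGB space.  Membership uses a
    strict inequality, so ``tolerance=0`` admits no pixel at all (not even
    the base color itself).
    """

    base_color: RGB
    tolerance: float

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError(f"tolerance must be >= 0, got {self.tolerance}")
        if len(self.base_color) != 3 or not all(
            0 <= c <= 255 for c in self.base_color
        ):
            raise ValueError(f"base_color must be an RGB triplet in [0, 255]^3, got {self.base_color}")


def color_distance(pixel: RGB, base: RGB) -> float:
    """Euclidean distance between two RGB triplets."""
    return math.sqrt(sum((float(a) - float(b)) ** 2 for a, b in zip(pixel, base)))


def in_range(pixel: RGB, color_range: ColorRange) -> bool:
    """True iff *pixel* lies strictly within the tolerance of the base color."""
    return color_distance(pixel, color_range.base_color) < color_range.tolerance


def build_mask(image: np.ndarray, color_range: ColorRange) -> np.ndarray:
    """Per-pixel boolean mask: True where the pixel color is in range."""
    rgb = np.asarray(image, dtype=np.float64)
    base = np.asarray(color_range.base_color, dtype=np.float64)
    dist_sq = ((rgb - base) ** 2).sum(axis=-1)
    return dist_sq < float(color_range.tolerance) ** 2


def preview_filtered(image: np.ndarray, color_range: ColorRange) -> np.ndarray:
    """Color-filtered preview: in-range pixels keep their color, the rest turn white."""
    mask = build_mask(image, color_range)
    out = np.full_like(np.asarray(image, dtype=np.uint8), 255)
    out[mask] = np.asarray(image, dtype=np.uint8)[mask]
    return out
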