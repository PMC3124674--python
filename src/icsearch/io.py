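"""Image and marker-file input/output.

Images are held as ``(height, width, 3)`` uint8 numpy arrays (RGB).  Marker
sets are ordered lists of ``(x, y)`` integer pixel coordinates, 0-based,
``x`` = column, ``y`` = row, origin at the top-left corner.

Cell locations are stored in a small tab-separated text format: a header
line ``# x<TAB>y`` followed by one ``x<TAB>y`` pair per marker.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

Marker = tuple[int, int]

MARKER_HEADER = "# x\ty"


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image into an RGB uint8 array.

    Grayscale images are promoted to RGB with R = G = B.  Images with more
    than 8 bits per sample are linearly rescaled so the maximum value present
    maps to 255.
    """
    try:
        img = Image.open(path)
        img.load()
    except FileNotFoundError:
        raise IOError(f"image file not found: {path}") from None
    except (UnidentifiedImageError, OSError) as exc:
        raise IOError(f"cannot read image {path!r}: {exc}") from exc

    if img.mode in ("I", "I;16", "I;16B", "I;16L", "I;16N", "F"):
        arr = np.asarray(img, dtype=np.float64)
        peak = arr.max()
        if peak > 0:
            arr = arr * (255.0 / peak)
        gray = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        return np.repeat(gray[:, :, None], 3, axis=2)

    rgb = np.asarray(img.convert("RGB"), dtype=np.uint8)
    return rgb


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB uint8 array (or a 2-D grayscale array) as an image file."""
    arr = np.asarray(image, dtype=np.uint8)
    try:
        Image.fromarray(arr).save(path)
    except OSError as exc:
        raise IOError(f"cannot write image {path!r}: {exc}") from exc


def save_markers(markers: Sequence[Marker], path: str | os.PathLike) -> None:
    """Write cell locations to a tab-separated text file."""
    try:
        with open(path, "w", encoding="ascii") as fh:
            fh.write(MARKER_HEADER + "\n")
            for x, y in markers:
                fh.write(f"{int(x)}\t{int(y)}\n")
    except OSError as exc:
        raise IOError(f"cannot write marker file {path!r}: {exc}") from exc


def load_markers(path: str | os.PathLike) -> list[Marker]:
    """Read a marker file written by :func:`save_markers`."""
    markers: list[Marker] = []
    try:
        with open(path, "r", encoding="ascii") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                xs, ys = line.split("\t")
                markers.append((int(xs), int(ys)))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot parse marker file {path!r}: {exc}") from exc
    return markers


def render_overlay(
    image: np.ndarray,
    markers: Sequence[Marker],
    dot_color: tuple[int, int, int] = (255, 255, 255),
) -> np.ndarray:
    """Return a copy of *image* with a 3x3 square drawn at every marker.

    Squares are clipped at the image borders.
    """
    out = np.array(image, dtype=np.uint8, copy=True)
    h, w = out.shape[:2]
    color = np.asarray(dot_color, dtype=np.uint8)
    for x, y in markers:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"marker ({x}, {y}) outside image bounds {w}x{h}")
        out[max(0, y - 1) : y + 2, max(0, x - 1) : x + 2] = color
    return out
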