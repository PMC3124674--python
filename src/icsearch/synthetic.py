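"""Ground-truth synthetic fixtures emulating stained tissue sections.

Two image families are emulated:

* DAB-like brightfield sections — sparse dark-brown disks (mitotic nuclei
  labeled with diaminobenzidine) on a near-white background;
* DAPI-like fluorescence sections — bright blue disks (DNA-stained nuclei)
  on a near-black background, optionally with a fraction of cells fused
  into a single saturated blob the way fluorescent signal bleeds between
  adjacent nuclei at low magnification.

Every fixture carries its exact ground-truth centers, so count-recovery
and placement can be scored without any real microscopy dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from PIL import Image

Marker = tuple[int, int]

DAB_STAIN = (101, 67, 33)
DAB_BACKGROUND = (245, 240, 235)
DAPI_STAIN = (40, 40, 255)
DAPI_BACKGROUND = (10, 10, 20)

#: Rejection-sampling retry cap per disk.
MAX_PLACEMENT_RETRIES = 10_000

# Cluster members sit this many diameters from an existing member of the
# same blob: close enough to overlap into one uniform region.
_CLUSTER_SPACING_RANGE = (0.55, 0.75)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic stained-section image.

    ``min_separation`` is center-to-center, applied between all non-cluster
    cells.  ``cluster_fraction`` of the cells are instead placed touching or
    overlapping each other, fusing into saturated blobs.  ``color_jitter_sd``
    is the per-channel Gaussian noise sigma, in 8-bit intensity units.
    """

    width: int = 512
    height: int = 400
    n_cells: int = 50
    cell_diameter: float = 23.0
    stain_color: tuple[int, int, int] = DAB_STAIN
    background_color: tuple[int, int, int] = DAB_BACKGROUND
    min_separation: float = 46.0
    color_jitter_sd: float = 8.0
    cluster_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"n_cells must be >= 0, got {self.n_cells}")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError(f"cluster_fraction must be in [0, 1], got {self.cluster_fraction}")
        if self.min_separation < 0:
            raise ValueError(f"min_separation must be >= 0, got {self.min_separation}")
        if self.cell_diameter <= 0:
            raise ValueError(f"cell_diameter must be > 0, got {self.cell_diameter}")
        if self.width < 1 or self.height < 1:
            raise ValueError(f"image dimensions must be >= 1, got {self.width}x{self.height}")


def dab_spec(**overrides) -> FixtureSpec:
    """DAB-like brightfield preset: sparse dark disks on a light background.

    Defaults follow the validation conditions of the original study: an
    average diameter of 23 px (200x magnification) and a few dozen labeled
    cells per field, well separated (two diameters apart center-to-center).
    """
    spec = FixtureSpec(
        stain_color=DAB_STAIN,
        background_color=DAB_BACKGROUND,
        n_cells=27,
        cell_diameter=23.0,
        min_separation=46.0,
    )
    return replace(spec, **overrides)


def dapi_spec(**overrides) -> FixtureSpec:
    """DAPI-like fluorescence preset: dense bright disks on a dark background.

    Nuclei are smaller and denser than in the DAB preset and a quarter of
    them fuse into saturated blobs, as fluorescent nuclei do when their
    boundaries blend at low magnification.
    """
    spec = FixtureSpec(
        stain_color=DAPI_STAIN,
        background_color=DAPI_BACKGROUND,
        n_cells=150,
        cell_diameter=12.0,
        min_separation=24.0,
        cluster_fraction=0.25,
    )
    return replace(spec, **overrides)


def _too_close(c: tuple[float, float], others: Sequence[tuple[float, float]], sep: float) -> bool:
    return any((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 < sep * sep for o in others)


def _place_centers(spec: FixtureSpec, rng: np.random.Generator) -> tuple[
    list[tuple[float, float]], list[tuple[float, float]]
]:
    """Rejection-sample disk centers; returns (separated, clustered) lists."""
    radius = spec.cell_diameter / 2.0
    lo_x, hi_x = radius, spec.width - radius
    lo_y, hi_y = radius, spec.height - radius
    if spec.n_cells > 0 and (lo_x >= hi_x or lo_y >= hi_y):
        raise ValueError(
            f"infeasible layout: a disk of diameter {spec.cell_diameter} does not "
            f"fit inside a {spec.width}x{spec.height} image"
        )

    n_cluster = int(round(spec.cluster_fraction * spec.n_cells))
    n_single = spec.n_cells - n_cluster
    singles: list[tuple[float, float]] = []
    clustered: list[tuple[float, float]] = []
    taken_pixels: set[Marker] = set()

    def sample_uniform() -> tuple[float, float]:
        return (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))

    def register(c: tuple[float, float]) -> bool:
        px = (int(round(c[0])), int(round(c[1])))
        if px in taken_pixels:
            return False
        taken_pixels.add(px)
        return True

    for k in range(n_single):
        for _ in range(MAX_PLACEMENT_RETRIES):
            c = sample_uniform()
            if _too_close(c, singles, spec.min_separation):
                continue
            if register(c):
                singles.append(c)
                break
        else:
            raise ValueError(
                f"infeasible layout: could not place separated disk {k + 1}/{n_single} "
                f"with min_separation={spec.min_separation} after "
                f"{MAX_PLACEMENT_RETRIES} retries"
            )

    spacing_lo = _CLUSTER_SPACING_RANGE[0] * spec.cell_diameter
    spacing_hi = _CLUSTER_SPACING_RANGE[1] * spec.cell_diameter
    for k in range(n_cluster):
        for _ in range(MAX_PLACEMENT_RETRIES):
            if not clustered:
                # Blob anchor: placed like a separated cell, away from singles.
                c = sample_uniform()
                if _too_close(c, singles, spec.min_separation):
                    continue
            else:
                host = clustered[rng.integers(len(clustered))]
                angle = rng.uniform(0.0, 2.0 * math.pi)
                dist = rng.uniform(spacing_lo, spacing_hi)
                c = (host[0] + dist * math.cos(angle), host[1] + dist * math.sin(angle))
                if not (lo_x <= c[0] <= hi_x and lo_y <= c[1] <= hi_y):
                    continue
                if _too_close(c, singles, spec.min_separation):
                    continue
            if register(c):
                clustered.append(c)
                break
        else:
            raise ValueError(
                f"infeasible layout: could not place clustered disk {k + 1}/{n_cluster} "
                f"after {MAX_PLACEMENT_RETRIES} retries"
            )
    return singles, clustered


def generate_fixture(spec: FixtureSpec) -> tuple[np.ndarray, list[Marker]]:
    """Render a synthetic stained section and its ground-truth centers.

    Returns an RGB uint8 image and the list of true disk centers (rounded
    to pixel coordinates, one per cell, in placement order).  Fully
    reproducible from ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    singles, clustered = _place_centers(spec, rng)
    centers = singles + clustered

    canvas = np.empty((spec.height, spec.width, 3), dtype=np.float64)
    canvas[:] = np.asarray(spec.background_color, dtype=np.float64)

    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    r_sq = (spec.cell_diameter / 2.0) ** 2
    stain = np.asarray(spec.stain_color, dtype=np.float64)
    for cx, cy in centers:
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_sq
        canvas[disk] = stain

    if spec.color_jitter_sd > 0:
        canvas += rng.normal(0.0, spec.color_jitter_sd, size=canvas.shape)

    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = [(int(round(cx)), int(round(cy))) for cx, cy in centers]
    return image, truth


def stain_mask(spec: FixtureSpec) -> np.ndarray:
    """Boolean mask of stain-covered pixels for the noise-free rendering."""
    clean = replace(spec, color_jitter_sd=0.0)
    image, _ = generate_fixture(clean)
    return np.all(image == np.asarray(spec.stain_color, dtype=np.uint8), axis=-1)


def resize_fixture(image: np.ndarray, factor: float) -> np.ndarray:
    """Bilinear resample of an RGB image by a scale factor."""
    if factor <= 0:
        raise ValueError(f"factor must be > 0, got {factor}")
    h, w = image.shape[:2]
    nw, nh = round(w * factor), round(h * factor)
    if nw < 1 or nh < 1:
        raise ValueError(f"factor {factor} collapses {w}x{h} below one pixel")
    if (nw, nh) == (w, h):
        return np.array(image, dtype=np.uint8, copy=True)
    resized = Image.fromarray(np.asarray(image, dtype=np.uint8)).resize(
        (nw, nh), resample=Image.BILINEAR
    )
    return np.asarray(resized, dtype=np.uint8)
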