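"""Independent oracles and fixture builders shared by the test suite.

The shortest-path oracles here deliberately avoid the package's own
traversal code: the pixel graph is materialized as an explicit sparse
adjacency matrix and solved with scipy's Dijkstra implementation.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from icsearch import ColorRange, FixtureSpec, ICSConfig, dab_spec, generate_fixture
from icsearch.synthetic import DAB_STAIN


def grid_graph(factor: np.ndarray, diag_cost: float = math.sqrt(2.0)) -> coo_matrix:
    """Directed 8-neighbor pixel graph; edge u->v weighs step * factor[v]."""
    h, w = factor.shape
    idx = np.arange(h * w).reshape(h, w)
    rows, cols, data = [], [], []
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            step = diag_cost if (dy != 0 and dx != 0) else 1.0
            src = idx[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
            tgt = idx[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)]
            rows.append(src.ravel())
            cols.append(tgt.ravel())
            data.append(step * factor.ravel()[tgt.ravel()])
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(h * w, h * w),
    )


def min_cost_field(
    factor: np.ndarray, seeds: list[tuple[int, int]], diag_cost: float = math.sqrt(2.0)
) -> np.ndarray:
    """Min-over-seeds single-source shortest-path costs, run to exhaustion."""
    h, w = factor.shape
    graph = grid_graph(factor, diag_cost).tocsr()
    ids = [y * w + x for x, y in seeds]
    dist = dijkstra(graph, directed=True, indices=ids, min_only=True)
    return dist.reshape(h, w)


def pairwise_path_costs(
    factor: np.ndarray, points: list[tuple[int, int]], diag_cost: float = math.sqrt(2.0)
) -> np.ndarray:
    """Shortest-path cost matrix between the given pixels."""
    h, w = factor.shape
    graph = grid_graph(factor, diag_cost).tocsr()
    ids = [y * w + x for x, y in points]
    dist = dijkstra(graph, directed=True, indices=ids)
    return dist[:, ids]


def state_factor(state) -> np.ndarray:
    """The per-pixel node-cost multiplier of a traversal state, as a 2-D array."""
    return np.asarray(state.factor, dtype=np.float64).reshape(state.height, state.width)


def random_fixture(rng: np.random.Generator, max_side: int = 30):
    """A small random image + config for oracle-equivalence style tests.

    Alternates between pure noise images and tiny disk renderings so both
    unstructured and structured cost fields are exercised.
    """
    h = int(rng.integers(8, max_side + 1))
    w = int(rng.integers(8, max_side + 1))
    if rng.random() < 0.5:
        image = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
        base = tuple(int(v) for v in rng.integers(0, 256, size=3))
    else:
        d = float(rng.uniform(4, 7))
        spec = FixtureSpec(
            width=w,
            height=h,
            n_cells=int(rng.integers(0, 3)),
            cell_diameter=d,
            min_separation=d,
            color_jitter_sd=float(rng.uniform(0, 10)),
            rng_seed=int(rng.integers(0, 2**31)),
        )
        try:
            image, _ = generate_fixture(spec)
        except ValueError:  # tiny canvas may not fit the requested disks
            image = rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8)
        base = DAB_STAIN
    cfg = ICSConfig(
        cell_diameter=float(rng.uniform(4, 8)),
        color_range=ColorRange(base, float(rng.uniform(60, 200))),
        edge_weight_factor=float(rng.uniform(0, 1)),
        resolution_scaling=bool(rng.random() < 0.5),
    )
    return image, cfg


def sized_dab_fixture(
    n_cells: int,
    diameter: float,
    rng_seed: int,
    separation_factor: float = 3.0,
    fill: float = 1.5,
):
    """A well-separated DAB-like fixture sized to hold ``n_cells`` disks.

    ``separation_factor`` is the minimum center-to-center distance in cell
    diameters; the canvas is sized so the requested layout stays far from
    the packing limit of rejection sampling.
    """
    sep = separation_factor * diameter
    area = n_cells * sep * sep * fill
    width = int(math.sqrt(area * 1.25))
    height = int(area / width)
    spec = dab_spec(
        n_cells=n_cells,
        cell_diameter=diameter,
        min_separation=sep,
        width=width,
        height=height,
        rng_seed=rng_seed,
    )
    return generate_fixture(spec), spec
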