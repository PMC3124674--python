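"""Counting performance metrics.

Two questions are answered here: how well do detected markers recover a
known ground truth (greedy one-to-one nearest matching within a radius),
and how consistent are the counts when the same image is processed at
several resolutions with a proportionally scaled cell diameter.  The
consistency statistic is the coefficient of variation (CV), the ratio of
the standard deviation to the mean of the counts.
"""

from __future__ import annotations

import csv
import dataclasses
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .search import ICSConfig, run_ics
from .synthetic import resize_fixture

Marker = tuple[int, int]


@dataclass(frozen=True)
class CountSeries:
    """Counts observed under a sequence of labelled conditions."""

    labels: tuple[str, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.counts):
            raise ValueError(
                f"{len(self.labels)} labels but {len(self.counts)} counts"
            )
        if any(c < 0 for c in self.counts):
            raise ValueError(f"counts must be >= 0, got {self.counts}")


def coefficient_of_variation(counts: Sequence[float]) -> float:
    """Sample standard deviation divided by the mean, as a fraction."""
    values = np.asarray(counts, dtype=np.float64)
    if values.size < 2:
        raise ValueError(f"CV requires at least 2 values, got {values.size}")
    mean = values.mean()
    if mean == 0:
        raise ValueError("CV is undefined for a series with zero mean")
    return float(values.std(ddof=1) / mean)


def multiresolution_run(
    image: np.ndarray, cfg: ICSConfig, factors: Sequence[float]
) -> CountSeries:
    """Count cells at several resolutions, rescaling the diameter with each.

    For each factor ``f`` the image is bilinearly resampled by ``f``, the
    configured cell diameter is multiplied by ``f``, and a full counting run
    records the marker total.
    """
    labels: list[str] = []
    counts: list[float] = []
    for f in factors:
        if f <= 0:
            raise ValueError(f"resolution factors must be > 0, got {f}")
        scaled = resize_fixture(image, f)
        scaled_cfg = dataclasses.replace(cfg, cell_diameter=cfg.cell_diameter * f)
        labels.append(f"{f:g}x")
        counts.append(float(len(run_ics(scaled, scaled_cfg))))
    return CountSeries(labels=tuple(labels), counts=tuple(counts))


def count_recovery(
    markers: Sequence[Marker], truth: Sequence[Marker], match_radius: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of markers against ground-truth centers.

    Candidate pairs within ``match_radius`` are matched in ascending order
    of distance; each marker and each truth point is used at most once.
    Returns ``(true_positives, false_positives, false_negatives)``.
    """
    if match_radius < 0:
        raise ValueError(f"match_radius must be >= 0, got {match_radius}")
    if not markers or not truth:
        return (0, len(markers), len(truth))

    det = np.asarray(markers, dtype=np.float64)
    ref = np.asarray(truth, dtype=np.float64)
    pairs: list[tuple[float, int, int]] = []
    tree = cKDTree(ref)
    for i, neighbors in enumerate(tree.query_ball_point(det, match_radius)):
        for j in neighbors:
            dist = float(np.hypot(*(det[i] - ref[j])))
            pairs.append((dist, i, j))
    pairs.sort()

    matched_det: set[int] = set()
    matched_ref: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in matched_det or j in matched_ref:
            continue
        matched_det.add(i)
        matched_ref.add(j)
        tp += 1
    return (tp, len(markers) - tp, len(truth) - tp)


def write_count_report(series: CountSeries, path: str | os.PathLike) -> None:
    """Write a CSV of (label, count) rows plus a CV summary line."""
    with open(path, "w", newline="", encoding="ascii") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "count"])
        for label, count in zip(series.labels, series.counts):
            writer.writerow([label, f"{count:g}"])
        writer.writerow(["cv", f"{coefficient_of_variation(series.counts):.6f}"])
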