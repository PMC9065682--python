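"""Density-based clustering of comparison units into labeled boxes.

Dots of one comparison unit are clustered with DBSCAN (Euclidean distance
on gene-rank coordinates, defaults eps=50, MinPts=3).  Each cluster is
summarised as the tight axis-aligned bounding box of its members; noise
dots belong to no box and are dropped from all downstream stages.  Box ids
are assigned top-to-bottom within the unit: 1, 2, ... by descending upper
edge l_y (ties broken by ascending left edge l_x).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .errors import ParameterError
from .model import ClusterBox, ComparisonUnit

__all__ = ["dbscan", "make_boxes", "cluster_unit", "DEFAULT_EPS", "DEFAULT_MIN_PTS"]

DEFAULT_EPS = 50.0
DEFAULT_MIN_PTS = 3


def dbscan(points: Sequence[tuple[float, float]], eps: float = DEFAULT_EPS,
           min_pts: int = DEFAULT_MIN_PTS) -> np.ndarray:
    """Cluster (x, y) rank pairs; returns one label per point, noise = -1.

    A core point has >= min_pts points (itself included) within Euclidean
    distance eps; clusters are the connected core points plus border
    points.  Given a fixed input order the labeling is deterministic:
    clusters are numbered in order of their first core point, and a border
    point reachable from several clusters joins the first one discovered.
    """
    if eps <= 0:
        raise ParameterError(f"eps must be > 0, got {eps}")
    if min_pts < 1:
        raise ParameterError(f"min_pts must be >= 1, got {min_pts}")
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pts)


def make_boxes(unit: ComparisonUnit, labels: Sequence[int]) -> list[ClusterBox]:
    """Bound each cluster of a unit; ids run top-to-bottom by l_y."""
    if len(labels) != len(unit.dots):
        raise ParameterError(
            f"{len(labels)} labels for {len(unit.dots)} dots"
        )
    clusters: dict[int, list] = {}
    for dot, label in zip(unit.dots, labels):
        if label < 0:  # noise
            continue
        clusters.setdefault(int(label), []).append(dot)
    raw = []
    for members in clusters.values():
        xs = [d.x for d in members]
        ys = [d.y for d in members]
        raw.append(
            ClusterBox(
                chr1=unit.target_chr, chr2=unit.ref_chr, id=0,
                l_x=min(xs), l_y=max(ys), r_x=max(xs), r_y=min(ys),
                num=len(members), members=tuple(members),
            )
        )
    raw.sort(key=lambda b: (-b.l_y, b.l_x))
    return [b.with_id(i) for i, b in enumerate(raw, start=1)]


def cluster_unit(unit: ComparisonUnit, eps: float = DEFAULT_EPS,
                 min_pts: int = DEFAULT_MIN_PTS) -> list[ClusterBox]:
    """DBSCAN one comparison unit and return its labeled boxes."""
    labels = dbscan([(d.x, d.y) for d in unit.dots], eps=eps, min_pts=min_pts)
    return make_boxes(unit, labels)
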