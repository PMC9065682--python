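"""Merging of clustered boxes into collinear regions.

Two boxes of the same comparison unit are merged when they are close
enough along both axes.  Distances are measured between the boxes'
projection intervals: ``y_gap``/``x_gap`` is positive when the intervals
are separated, zero when touching, negative when overlapping.  The rules:

* disjoint on both axes: merge iff 0 <= y_gap <= gap and 0 <= x_gap <= Slen;
* overlapping in y only:  merge iff 0 <= x_gap <  Slen;
* overlapping in x only:  merge iff 0 <= y_gap <= gap;
* overlapping on both axes (nested/crossing boxes): always merge.

``gap`` is the mean positive vertical gap between vertically adjacent
boxes of the unit (computed once, before any merging); ``Slen`` is 1/6 of
the target chromosome's length.  Boxes with fewer than ``min_num`` gene
pairs are discarded before merging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .errors import LogicError, ParameterError
from .model import ClusterBox

__all__ = [
    "MergeParams",
    "interval_gap",
    "compute_gap",
    "should_merge",
    "merge_unit",
    "DEFAULT_MIN_NUM",
    "SLEN_DIVISOR",
]

DEFAULT_MIN_NUM = 5
#: Slen = target chromosome length / SLEN_DIVISOR
SLEN_DIVISOR = 6.0


@dataclass(frozen=True)
class MergeParams:
    """Merge thresholds for one comparison unit."""

    gap: float          # mean vertical gap between adjacent boxes, rank units
    slen: float         # 1/6 of the target chromosome length, rank units
    min_num: int = DEFAULT_MIN_NUM

    def __post_init__(self):
        if self.gap < 0:
            raise ParameterError(f"gap must be >= 0, got {self.gap}")
        if self.slen <= 0:
            raise ParameterError(f"slen must be > 0, got {self.slen}")


def interval_gap(a_lo: float, a_hi: float, b_lo: float, b_hi: float) -> float:
    """Signed distance between intervals [a_lo,a_hi] and [b_lo,b_hi].

    Positive = separation, 0 = touching, negative = overlap depth.
    """
    if a_lo > a_hi or b_lo > b_hi:
        raise ParameterError("interval bounds out of order")
    return max(b_lo - a_hi, a_lo - b_hi)


def compute_gap(boxes: Sequence[ClusterBox]) -> float:
    """Mean positive vertical gap between consecutive boxes (top to bottom).

    Boxes are ordered by descending upper edge; overlapping neighbours
    contribute nothing.  Returns 0 for a single box or when no positive
    gap exists.
    """
    if not boxes:
        raise ParameterError("compute_gap requires at least one box")
    ordered = sorted(boxes, key=lambda b: (-b.l_y, b.r_y))
    gaps = []
    for upper, lower in zip(ordered, ordered[1:]):
        g = upper.r_y - lower.l_y
        if g > 0:
            gaps.append(g)
    return sum(gaps) / len(gaps) if gaps else 0.0


def should_merge(a: ClusterBox, b: ClusterBox, p: MergeParams) -> bool:
    """Apply the gap rules to one pair of boxes of the same unit."""
    if (a.chr1, a.chr2) != (b.chr1, b.chr2):
        raise LogicError(
            f"boxes from different units: ({a.chr1},{a.chr2}) vs "
            f"({b.chr1},{b.chr2})"
        )
    y_gap = interval_gap(a.r_y, a.l_y, b.r_y, b.l_y)
    x_gap = interval_gap(a.l_x, a.r_x, b.l_x, b.r_x)
    y_overlap = y_gap < 0
    x_overlap = x_gap < 0
    if y_overlap and x_overlap:
        return True
    if y_overlap:
        return 0 <= x_gap < p.slen
    if x_overlap:
        return 0 <= y_gap <= p.gap
    return y_gap <= p.gap and x_gap <= p.slen


def _union(a: ClusterBox, b: ClusterBox) -> ClusterBox:
    return replace(
        a,
        l_x=min(a.l_x, b.l_x), l_y=max(a.l_y, b.l_y),
        r_x=max(a.r_x, b.r_x), r_y=min(a.r_y, b.r_y),
        num=a.num + b.num, members=a.members + b.members,
    )


def merge_unit(boxes: Sequence[ClusterBox], p: MergeParams) -> list[ClusterBox]:
    """Merge the boxes of one comparison unit to a fixpoint.

    Boxes below ``p.min_num`` gene pairs are dropped first.  Pairs are
    scanned in a fixed order and the first mergeable pair is replaced by
    its union bounding box (num = sum, members = union) until no pair
    merges; ids are then reassigned top-to-bottom.  The fixpoint makes
    merging transitive: a chain A–B, B–C merges all three even if A and C
    are not directly mergeable.
    """
    active = [b for b in sorted(boxes, key=lambda b: b.id) if b.num >= p.min_num]
    merged_any = True
    while merged_any:
        merged_any = False
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                if should_merge(active[i], active[j], p):
                    union = _union(active[i], active[j])
                    active = (active[:i] + [union] + active[i + 1:j]
                              + active[j + 1:])
                    merged_any = True
                    break
            if merged_any:
                break
    active.sort(key=lambda b: (-b.l_y, b.l_x))
    return [b.with_id(i) for i, b in enumerate(active, start=1)]
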