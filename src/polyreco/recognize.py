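"""Polyploidy recognition from labeled collinear regions.

For each reference chromosome the merged boxes (pooled over all target
chromosomes) are grouped into *combination rounds*: a round is a set of
boxes whose projections on the reference axis are pairwise disjoint, so
together they tile (part of) the reference chromosome — one retained
collinear copy.  Rounds are built greedily: seed on the longest remaining
box, then choose, by exhaustive search, the y-disjoint companion set that
maximises the round's total length ``sumy``.  Each round is scored with
the collinearity evaluation index

    MI = sumy / len_i

(the fraction of reference chromosome i covered by the round).  Plotted
against the round index, MI stays high for as many rounds as there are
retained genome copies and then collapses; the round with the largest
drop (the inflection) is the multiplication level of that chromosome, and
the modal level across chromosomes is the genome-wide call: 2 = whole
genome duplication, 3 = whole genome triplication.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import replace
from typing import Mapping, Sequence

from .errors import ParameterError
from .model import ClusterBox, CombinationRound, PloidyCall, natural_key

__all__ = [
    "build_round",
    "enumerate_rounds",
    "compute_mi",
    "detect_inflection",
    "call_ploidy",
    "boxes_by_ref_chr",
]


def _y_disjoint(a: ClusterBox, b: ClusterBox, tol: float = 0.0) -> bool:
    """True when the boxes' reference-axis intervals overlap by <= tol.

    With the default tol=0, closed intervals may share an endpoint but not
    interior.
    """
    return min(a.l_y, b.l_y) - max(a.r_y, b.r_y) <= tol


def _tie_key(members: Sequence[ClusterBox]):
    return (len(members), sorted((str(b.chr1), b.id) for b in members))


def build_round(unused: Sequence[ClusterBox], y_tol: float = 0.0) -> CombinationRound:
    """Build one combination round from the not-yet-used boxes.

    The seed is the box with the largest delta_y (ties: larger num, then
    smaller r_y).  Members are the seed plus a y-disjoint subset of the
    remaining boxes, each no longer than the seed, chosen by exhaustive
    search to maximise sumy.  Equal-sumy subsets are resolved toward fewer
    members, then the lexicographically smallest (chr1, id) list.
    """
    boxes = list(unused)
    if not boxes:
        raise ParameterError("build_round requires at least one box")
    seed = max(boxes, key=lambda b: (b.delta_y, b.num, -b.r_y))
    cands = [
        b for b in boxes
        if b is not seed and b.delta_y <= seed.delta_y
        and _y_disjoint(b, seed, y_tol)
    ]
    cands.sort(key=lambda b: (b.r_y, b.l_y))
    suffix = [0] * (len(cands) + 1)
    for i in range(len(cands) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + cands[i].delta_y

    best_members = [seed]
    best_sum = seed.delta_y
    best_tie = _tie_key(best_members)

    def consider(chosen: list[ClusterBox], total: int) -> None:
        nonlocal best_members, best_sum, best_tie
        members = [seed] + chosen
        tie = _tie_key(members)
        if total > best_sum or (total == best_sum and tie < best_tie):
            best_members, best_sum, best_tie = members, total, tie

    def dfs(start: int, chosen: list[ClusterBox], total: int) -> None:
        consider(chosen, total)
        for j in range(start, len(cands)):
            # branches that cannot beat the incumbent are cut; equal-sum
            # branches survive so the tie rules stay exact
            if total + suffix[j] < best_sum:
                return
            b = cands[j]
            if all(_y_disjoint(b, c, y_tol) for c in chosen):
                chosen.append(b)
                dfs(j + 1, chosen, total + b.delta_y)
                chosen.pop()

    dfs(0, [], seed.delta_y)
    ordered = tuple(sorted(best_members, key=lambda b: -b.delta_y))
    return CombinationRound(ref_chr=seed.chr2, comro=0, members=ordered,
                            sumy=best_sum)


def enumerate_rounds(boxes: Sequence[ClusterBox], ref_len: int | None = None,
                     y_tol: float = 0.0) -> list[CombinationRound]:
    """Exhaustively group boxes of one reference chromosome into rounds.

    build_round is applied repeatedly to the remaining boxes until none is
    left; rounds are numbered 1, 2, ... and scored with MI when the
    reference chromosome length is supplied.
    """
    remaining = list(boxes)
    rounds: list[CombinationRound] = []
    while remaining:
        rnd = build_round(remaining, y_tol=y_tol)
        used = {id(m) for m in rnd.members}
        remaining = [b for b in remaining if id(b) not in used]
        rounds.append(rnd)
    # the greedy longest-seed order makes sumy non-increasing in practice;
    # re-sort defensively so the round index is always coverage-ranked
    rounds.sort(key=lambda r: -r.sumy)
    return [
        replace(r, comro=i,
                mi=compute_mi(r, ref_len) if ref_len is not None else None)
        for i, r in enumerate(rounds, start=1)
    ]


def compute_mi(rnd: CombinationRound, ref_len: int) -> float:
    """Collinearity evaluation index: sumy / reference chromosome length."""
    if ref_len <= 0:
        raise ParameterError(f"reference length must be > 0, got {ref_len}")
    mi = rnd.sumy / ref_len
    if mi > 1:
        warnings.warn(
            f"MI {mi:.2%} exceeds 100% on chromosome {rnd.ref_chr}: boxes "
            "over-cover the reference axis (check the length table)",
            stacklevel=2,
        )
    return mi


def detect_inflection(mi_series: Sequence[float]) -> int:
    """Round index after which MI drops the most (1-based).

    The series is extended with MI = 0 past the last round, so a single
    high round yields 1.  Ties go to the smaller index.
    """
    series = list(mi_series)
    if not series:
        raise ParameterError("detect_inflection requires a non-empty series")
    extended = series + [0.0]
    drops = [extended[i] - extended[i + 1] for i in range(len(series))]
    best = max(drops)
    return drops.index(best) + 1


def call_ploidy(per_chr_inflections: Mapping[str, int],
                mi_series: Mapping[str, Sequence[float]] | None = None) -> PloidyCall:
    """Consensus multiplier: the modal inflection round across chromosomes.

    Ties resolve to the smaller multiplier; chromosomes disagreeing with
    the consensus are reported as dissenting.
    """
    if not per_chr_inflections:
        raise ParameterError("call_ploidy requires at least one chromosome")
    counts = Counter(per_chr_inflections.values())
    top = max(counts.values())
    multiplier = min(k for k, c in counts.items() if c == top)
    dissenting = tuple(sorted(
        (c for c, k in per_chr_inflections.items() if k != multiplier),
        key=natural_key,
    ))
    return PloidyCall(per_chr=dict(per_chr_inflections), multiplier=multiplier,
                      dissenting=dissenting, mi_series=mi_series)


def boxes_by_ref_chr(boxes: Sequence[ClusterBox]) -> dict[str, list[ClusterBox]]:
    """Pool boxes over target chromosomes, keyed by reference chromosome."""
    grouped: dict[str, list[ClusterBox]] = {}
    for b in boxes:
        grouped.setdefault(b.chr2, []).append(b)
    return dict(sorted(grouped.items(), key=lambda kv: natural_key(kv[0])))
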