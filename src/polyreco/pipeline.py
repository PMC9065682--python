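"""End-to-end pipeline: dots -> clusters -> merged regions -> ploidy call."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cluster import DEFAULT_EPS, DEFAULT_MIN_PTS, cluster_unit
from .dotplot import filter_ks, group_units
from .errors import ParameterError
from .merge import DEFAULT_MIN_NUM, SLEN_DIVISOR, MergeParams, compute_gap, merge_unit
from .model import ChromosomeLengths, ClusterBox, CombinationRound, HomologDot, PloidyCall
from .recognize import (
    boxes_by_ref_chr,
    call_ploidy,
    detect_inflection,
    enumerate_rounds,
)

__all__ = ["PipelineParams", "RunResult", "cluster_stage", "merge_stage",
           "recognize_stage", "run"]

log = logging.getLogger("polyreco")


@dataclass(frozen=True)
class PipelineParams:
    """All tunable knobs of the pipeline with their defaults."""

    eps: float = DEFAULT_EPS
    min_pts: int = DEFAULT_MIN_PTS
    min_num: int = DEFAULT_MIN_NUM
    ks_min: float = 0.0
    ks_max: float = 2.0
    y_overlap_tol: float = 0.0
    #: reference chromosomes with fewer merged boxes are skipped by the caller
    min_boxes_per_chr: int = 2
    #: restrict analysis to these reference chromosomes (None = all)
    ref_chrs: tuple[str, ...] | None = None


@dataclass
class RunResult:
    clusters: list[ClusterBox]
    merged: list[ClusterBox]
    rounds_by_chr: dict[str, list[CombinationRound]]
    call: PloidyCall | None


def cluster_stage(dots: list[HomologDot],
                  params: PipelineParams = PipelineParams()) -> list[ClusterBox]:
    """Ks-filter, split into comparison units and DBSCAN each unit."""
    kept = filter_ks(dots, params.ks_min, params.ks_max)
    boxes: list[ClusterBox] = []
    for unit in group_units(kept):
        boxes.extend(cluster_unit(unit, eps=params.eps, min_pts=params.min_pts))
    log.info("clustered %d dots into %d boxes", len(kept), len(boxes))
    return boxes


def merge_stage(boxes: list[ClusterBox], target_lens: ChromosomeLengths,
                params: PipelineParams = PipelineParams()) -> list[ClusterBox]:
    """Merge each unit's boxes into collinear regions via the gap rules."""
    by_unit: dict[tuple[str, str], list[ClusterBox]] = {}
    for b in boxes:
        by_unit.setdefault((b.chr1, b.chr2), []).append(b)
    merged: list[ClusterBox] = []
    for (chr1, _chr2), unit_boxes in by_unit.items():
        kept = [b for b in unit_boxes if b.num >= params.min_num]
        if not kept:
            continue
        if chr1 not in target_lens:
            raise ParameterError(
                f"target chromosome {chr1!r} missing from the length table"
            )
        p = MergeParams(
            gap=compute_gap(kept),
            slen=target_lens[chr1] / SLEN_DIVISOR,
            min_num=params.min_num,
        )
        merged.extend(merge_unit(kept, p))
    log.info("merged %d boxes into %d collinear regions", len(boxes), len(merged))
    return merged


def recognize_stage(merged: list[ClusterBox], ref_lens: ChromosomeLengths,
                    params: PipelineParams = PipelineParams()) -> RunResult:
    """Group merged regions into rounds per reference chromosome and call ploidy."""
    grouped = boxes_by_ref_chr(merged)
    if params.ref_chrs is not None:
        wanted = {str(c) for c in params.ref_chrs}
        grouped = {c: bx for c, bx in grouped.items() if c in wanted}
    rounds_by_chr: dict[str, list[CombinationRound]] = {}
    inflections: dict[str, int] = {}
    mi_series: dict[str, list[float]] = {}
    for ref_chr, chr_boxes in grouped.items():
        if len(chr_boxes) < params.min_boxes_per_chr:
            log.info("skipping reference chromosome %s: only %d region(s)",
                     ref_chr, len(chr_boxes))
            continue
        if ref_chr not in ref_lens:
            raise ParameterError(
                f"reference chromosome {ref_chr!r} missing from the length table"
            )
        rounds = enumerate_rounds(chr_boxes, ref_len=ref_lens[ref_chr],
                                  y_tol=params.y_overlap_tol)
        rounds_by_chr[ref_chr] = rounds
        mi_series[ref_chr] = [r.mi for r in rounds]
        inflections[ref_chr] = detect_inflection(mi_series[ref_chr])
    call = call_ploidy(inflections, mi_series) if inflections else None
    return RunResult(clusters=[], merged=merged, rounds_by_chr=rounds_by_chr,
                     call=call)


def run(dots: list[HomologDot], target_lens: ChromosomeLengths,
        ref_lens: ChromosomeLengths,
        params: PipelineParams = PipelineParams()) -> RunResult:
    """Full pipeline from raw dots to the ploidy call."""
    clusters = cluster_stage(dots, params)
    merged = merge_stage(clusters, target_lens, params)
    result = recognize_stage(merged, ref_lens, params)
    result.clusters = clusters
    return result
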