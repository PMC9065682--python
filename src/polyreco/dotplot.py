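"""Dotplot assembly: Ks display-range filtering and comparison units.

A comparison unit is the cell of the dotplot formed by one target
chromosome crossed with one reference chromosome; clustering and merging
operate strictly within a unit.
"""

from __future__ import annotations

from typing import Iterable

from .errors import ParameterError
from .model import ComparisonUnit, HomologDot, natural_key

__all__ = ["filter_ks", "group_units"]


def filter_ks(dots: Iterable[HomologDot], ks_min: float = 0.0,
              ks_max: float = 2.0) -> list[HomologDot]:
    """Keep dots with ks_min <= ks <= ks_max (the displayed Ks range)."""
    if ks_min > ks_max:
        raise ParameterError(f"ks_min ({ks_min}) > ks_max ({ks_max})")
    return [d for d in dots if ks_min <= d.ks <= ks_max]


def group_units(dots: Iterable[HomologDot]) -> list[ComparisonUnit]:
    """Partition dots into per-(target, reference)-chromosome units.

    Units are sorted by (reference chromosome, target chromosome) with
    numeric names in numeric order; dot order within a unit follows the
    input order.
    """
    by_pair: dict[tuple[str, str], ComparisonUnit] = {}
    for d in dots:
        key = (d.target_chr, d.ref_chr)
        unit = by_pair.get(key)
        if unit is None:
            unit = by_pair[key] = ComparisonUnit(d.target_chr, d.ref_chr)
        unit.dots.append(d)
    return sorted(
        by_pair.values(),
        key=lambda u: (natural_key(u.ref_chr), natural_key(u.target_chr)),
    )
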