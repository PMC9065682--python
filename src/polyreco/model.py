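"""Core in-memory data types.

Coordinates throughout the package are *gene-order ranks*: the n-th gene on a
chromosome has rank n.  A homologous gene pair between a target genome (x
axis) and a reference genome (y axis) is a dot in that rank plane, coloured
by its synonymous substitution rate (Ks).  Collinear regions appear as
diagonal runs of dots and are summarised as axis-aligned bounding boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import ParameterError

__all__ = [
    "HomologDot",
    "ChromosomeLengths",
    "ComparisonUnit",
    "ClusterBox",
    "CombinationRound",
    "PloidyCall",
    "natural_key",
]


def natural_key(name: str):
    """Sort key placing numeric chromosome names in numeric order.

    "2" sorts before "13"; purely textual names sort after numeric ones,
    alphabetically.
    """
    s = str(name)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass(frozen=True)
class HomologDot:
    """One homologous gene pair: a point on the Ks dotplot.

    ``x``/``y`` are 1-based gene-order ranks on the target / reference
    chromosome; ``ks`` is the synonymous substitution rate of the pair.
    """

    target_chr: str
    x: int
    ref_chr: str
    y: int
    ks: float

    def __post_init__(self):
        if self.x < 1 or self.y < 1:
            raise ParameterError(
                f"gene ranks must be >= 1, got x={self.x}, y={self.y}"
            )
        if not math.isfinite(self.ks) or self.ks < 0:
            raise ParameterError(f"ks must be finite and >= 0, got {self.ks}")


@dataclass
class ChromosomeLengths:
    """Per-species map from chromosome name to length in gene-rank units."""

    entries: dict[str, int]
    species: str | None = None

    def __post_init__(self):
        for name, length in self.entries.items():
            if length <= 0:
                raise ParameterError(
                    f"chromosome {name!r}: length must be positive, got {length}"
                )

    def __getitem__(self, chrom: str) -> int:
        return self.entries[str(chrom)]

    def __contains__(self, chrom: str) -> bool:
        return str(chrom) in self.entries

    def get(self, chrom: str, default=None):
        return self.entries.get(str(chrom), default)

    def items(self):
        return self.entries.items()

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ComparisonUnit:
    """All dots of one (target chromosome, reference chromosome) cell."""

    target_chr: str
    ref_chr: str
    dots: list[HomologDot] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.dots)


@dataclass(frozen=True)
class ClusterBox:
    """Axis-aligned bounding box of one dot cluster (a collinear region).

    ``(l_x, l_y)`` is the upper-left corner and ``(r_x, r_y)`` the
    lower-right corner, with y increasing toward the top of the box:
    ``l_x <= r_x`` and ``r_y <= l_y``.  ``num`` counts the homologous gene
    pairs inside; ``members`` retains them when the box was built from dots
    (boxes read back from CSV carry an empty tuple).
    """

    chr1: str  # target chromosome
    chr2: str  # reference chromosome
    id: int
    l_x: int
    l_y: int
    r_x: int
    r_y: int
    num: int
    members: tuple[HomologDot, ...] = ()

    def __post_init__(self):
        if self.l_x > self.r_x or self.r_y > self.l_y:
            raise ParameterError(
                f"invalid box corners: l=({self.l_x},{self.l_y}) "
                f"r=({self.r_x},{self.r_y})"
            )
        if self.num < 0:
            raise ParameterError(f"num must be >= 0, got {self.num}")

    @property
    def delta_y(self) -> int:
        """Box length along the reference axis (l_y - r_y)."""
        return self.l_y - self.r_y

    @property
    def delta_x(self) -> int:
        """Box width along the target axis (r_x - l_x)."""
        return self.r_x - self.l_x

    @property
    def y_interval(self) -> tuple[int, int]:
        return (self.r_y, self.l_y)

    @property
    def x_interval(self) -> tuple[int, int]:
        return (self.l_x, self.r_x)

    def with_id(self, new_id: int) -> "ClusterBox":
        return replace(self, id=new_id)


@dataclass(frozen=True)
class CombinationRound:
    """One combination round: y-disjoint boxes covering a reference chromosome.

    ``sumy`` is the total box length (sum of member delta_y) and ``mi`` the
    collinearity evaluation index sumy / reference-chromosome length (a
    fraction; reported as a percentage in outputs).
    """

    ref_chr: str
    comro: int
    members: tuple[ClusterBox, ...]
    sumy: int
    mi: float | None = None


@dataclass(frozen=True)
class PloidyCall:
    """Aggregated ploidy-multiplier call over the analysed reference chromosomes."""

    per_chr: Mapping[str, int]
    multiplier: int
    dissenting: tuple[str, ...] = ()
    mi_series: Mapping[str, Sequence[float]] | None = None

    @property
    def interpretation(self) -> str:
        names = {1: "no recent multiplication", 2: "whole-genome duplication",
                 3: "whole-genome triplication"}
        return names.get(self.multiplier, f"{self.multiplier}-fold multiplication")
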