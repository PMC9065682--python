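"""Synthetic Ks dotplots with planted polyploidy structure.

The generator emulates the dotplot of a target genome that is a k-fold
polyploid relative to a reference: every reference chromosome is copied k
times onto distinct target chromosomes (random offsets, random diagonal
orientation), each copy loses genes independently (``retention``), is cut
into fragments at uniform breakpoints with rank jitter between fragments,
and carries Ks values drawn from a truncated normal around the event's
age.  Optional extra layers plant older, sparser events (e.g. an ancient
triplication at Ks ~ 1.5 behind a recent duplication at Ks ~ 0.3), and
uniform background noise dots are sprinkled over every comparison unit.

Target chromosomes are assembled by concatenating their assigned copies
with random spacers, which mirrors how real polyploid chromosomes carry
several ancestral segments end to end; chromosome lengths follow from the
content.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .model import ChromosomeLengths, HomologDot

__all__ = ["LayerConfig", "SimConfig", "CopySegment", "SimTruth", "SimResult",
           "simulate"]


@dataclass(frozen=True)
class LayerConfig:
    """One polyploidy event layer (multiplier copies at a given Ks age)."""

    multiplier: int
    retention: float
    ks_mean: float
    ks_sd: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dotplot.

    Defaults describe a mid-sized plant comparison: three reference
    chromosomes of 800 genes each against eight target chromosomes, a
    recent event at Ks ~ 0.3, 70% gene retention per copy, two
    fragmentation breaks per copy and a light uniform noise background.
    """

    n_ref_chr: int = 3
    genes_per_ref_chr: int = 800
    multiplier: int = 2
    n_target_chr: int = 8
    retention: float = 0.7
    n_breaks: int = 2
    ks_mean: float = 0.3
    ks_sd: float = 0.08
    noise_rate: float = 2e-5  # background dots per unit of rank area
    seed: int = 0
    extra_layers: tuple[LayerConfig, ...] = ()
    fragment_jitter: tuple[int, int] = (10, 40)   # rank gap inserted per break
    copy_spacing: tuple[int, int] = (30, 120)     # pad before each copy

    def __post_init__(self):
        if self.multiplier < 1:
            raise ParameterError(f"multiplier must be >= 1, got {self.multiplier}")
        if not 0 < self.retention <= 1:
            raise ParameterError(f"retention must be in (0, 1], got {self.retention}")
        if min(self.n_ref_chr, self.genes_per_ref_chr, self.n_target_chr) < 1:
            raise ParameterError("chromosome and gene counts must be >= 1")
        if self.n_breaks < 0 or self.noise_rate < 0:
            raise ParameterError("n_breaks and noise_rate must be >= 0")
        top = max([self.multiplier] + [l.multiplier for l in self.extra_layers])
        if self.n_target_chr < top:
            raise ParameterError(
                f"cannot place {top} copies of one reference chromosome on "
                f"{self.n_target_chr} distinct target chromosomes"
            )


@dataclass(frozen=True)
class CopySegment:
    """Ground truth for one planted copy of a reference chromosome."""

    ref_chr: str
    target_chr: str
    y_lo: int
    y_hi: int
    x_lo: int
    x_hi: int
    orientation: int  # +1 main diagonal, -1 anti-diagonal


@dataclass(frozen=True)
class SimTruth:
    """Planted structure of the main (most recent) event layer."""

    multiplier: int
    segments: dict[str, tuple[CopySegment, ...]] = field(default_factory=dict)


class SimResult(NamedTuple):
    dots: list[HomologDot]
    target_lens: ChromosomeLengths
    ref_lens: ChromosomeLengths
    truth: SimTruth


def _plant_layer(rng: np.random.Generator, cfg: SimConfig, layer: LayerConfig,
                 cursors: dict[str, int], dots: list[HomologDot],
                 record: dict[str, list[CopySegment]] | None) -> None:
    targets = list(cursors)
    genes = cfg.genes_per_ref_chr
    for r in range(1, cfg.n_ref_chr + 1):
        ref = str(r)
        homes = rng.choice(len(targets), size=layer.multiplier, replace=False)
        for t_idx in homes:
            target = targets[int(t_idx)]
            orientation = 1 if rng.random() < 0.5 else -1
            cursor = cursors[target] + int(rng.integers(*cfg.copy_spacing))
            x_lo = cursor + 1
            if cfg.n_breaks > 0 and genes > 2:
                k = min(cfg.n_breaks, genes - 2)
                cuts = set(int(c) for c in
                           rng.choice(np.arange(2, genes), size=k, replace=False))
            else:
                cuts = set()
            ys = range(1, genes + 1) if orientation == 1 else range(genes, 0, -1)
            for y in ys:
                if y in cuts:  # new fragment: shift following ranks
                    cursor += int(rng.integers(*cfg.fragment_jitter))
                if rng.random() < layer.retention:
                    cursor += 1
                    ks = abs(rng.normal(layer.ks_mean, layer.ks_sd))
                    dots.append(HomologDot(target, cursor, ref, y, ks))
            cursors[target] = cursor
            if record is not None:
                record.setdefault(ref, []).append(
                    CopySegment(ref, target, 1, genes, x_lo, max(x_lo, cursor),
                                orientation)
                )


def simulate(config: SimConfig) -> SimResult:
    """Generate a dotplot, the two length tables and the planted truth."""
    rng = np.random.default_rng(config.seed)
    cursors = {str(t): 0 for t in range(1, config.n_target_chr + 1)}
    dots: list[HomologDot] = []
    truth_segments: dict[str, list[CopySegment]] = {}

    main = LayerConfig(config.multiplier, config.retention,
                       config.ks_mean, config.ks_sd)
    _plant_layer(rng, config, main, cursors, dots, truth_segments)
    for layer in config.extra_layers:
        _plant_layer(rng, config, layer, cursors, dots, None)

    target_lens = ChromosomeLengths(
        {t: max(c + int(rng.integers(20, 80)), 200) for t, c in cursors.items()},
        species="target",
    )
    ref_lens = ChromosomeLengths(
        {str(r): config.genes_per_ref_chr for r in range(1, config.n_ref_chr + 1)},
        species="reference",
    )

    if config.noise_rate > 0:
        for target, tlen in target_lens.items():
            for ref, rlen in ref_lens.items():
                n = int(rng.poisson(config.noise_rate * tlen * rlen))
                if n == 0:
                    continue
                xs = rng.integers(1, tlen + 1, size=n)
                ys = rng.integers(1, rlen + 1, size=n)
                kss = rng.uniform(0.0, 2.0, size=n)
                dots.extend(
                    HomologDot(target, int(x), ref, int(y), float(k))
                    for x, y, k in zip(xs, ys, kss)
                )

    truth = SimTruth(
        multiplier=config.multiplier,
        segments={r: tuple(segs) for r, segs in truth_segments.items()},
    )
    return SimResult(dots, target_lens, ref_lens, truth)
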