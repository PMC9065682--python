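"""Figures: labeled dotplot, MI line chart, combination figure.

Chromosomes are laid out on concatenated rank axes with the reference
chromosomes running top to bottom, matching the usual orientation of Ks
dotplots.  The Ks colour scale is fixed to the displayed range 0–2.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .model import ChromosomeLengths, ClusterBox, CombinationRound, HomologDot, natural_key

__all__ = ["plot_dotplot", "plot_mi_curves", "plot_combination"]

KS_CMAP = "gist_rainbow"
KS_RANGE = (0.0, 2.0)


def _offsets(lens: ChromosomeLengths) -> tuple[dict[str, int], int]:
    """Cumulative start offset per chromosome (natural name order)."""
    offsets: dict[str, int] = {}
    total = 0
    for name in sorted(lens.entries, key=natural_key):
        offsets[name] = total
        total += lens[name]
    return offsets, total


def plot_dotplot(dots: Sequence[HomologDot], boxes: Sequence[ClusterBox],
                 target_lens: ChromosomeLengths, ref_lens: ChromosomeLengths,
                 path: str, title: str = "Ks dotplot") -> None:
    """Scatter the dots coloured by Ks with region rectangles overlaid."""
    x_off, x_total = _offsets(target_lens)
    y_off, y_total = _offsets(ref_lens)
    fig, ax = plt.subplots(figsize=(9, 8))
    if dots:
        xs = [x_off[d.target_chr] + d.x for d in dots]
        ys = [y_off[d.ref_chr] + d.y for d in dots]
        sc = ax.scatter(xs, ys, c=[d.ks for d in dots], s=2, cmap=KS_CMAP,
                        vmin=KS_RANGE[0], vmax=KS_RANGE[1], linewidths=0)
        fig.colorbar(sc, ax=ax, label="Ks")
    for b in boxes:
        ax.add_patch(Rectangle(
            (x_off[b.chr1] + b.l_x, y_off[b.chr2] + b.r_y),
            b.delta_x, b.delta_y, fill=False, edgecolor="black", linewidth=0.8,
        ))
    for name, off in x_off.items():
        ax.axvline(off, color="grey", linewidth=0.4)
        ax.text(off + target_lens[name] / 2, -0.02 * y_total, name,
                ha="center", va="top", fontsize=7)
    for name, off in y_off.items():
        ax.axhline(off, color="grey", linewidth=0.4)
        ax.text(-0.02 * x_total, off + ref_lens[name] / 2, name,
                ha="right", va="center", fontsize=7)
    ax.set_xlim(0, x_total)
    ax.set_ylim(y_total, 0)  # reference chromosomes read top to bottom
    ax.set_xlabel("target genome (gene rank)")
    ax.set_ylabel("reference genome (gene rank)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mi_curves(mi_by_chr: Mapping[str, Sequence[float]], path: str) -> None:
    """Collinearity-index line chart: MI (%) against combination round."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for chrom in sorted(mi_by_chr, key=natural_key):
        series = [100 * v for v in mi_by_chr[chrom]]
        rounds = range(1, len(series) + 1)
        ax.plot(rounds, series, marker="o", label=f"chr {chrom}")
    ax.set_xlabel("combination round")
    ax.set_ylabel("MI (%)")
    ax.set_ylim(bottom=0)
    ax.xaxis.get_major_locator().set_params(integer=True)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_combination(rounds_by_chr: Mapping[str, Sequence[CombinationRound]],
                     ref_lens: ChromosomeLengths, path: str) -> None:
    """Per chromosome, stack each round's member regions along the reference axis."""
    chroms = sorted(rounds_by_chr, key=natural_key)
    fig, axes = plt.subplots(1, max(len(chroms), 1),
                             figsize=(3.2 * max(len(chroms), 1), 4.5),
                             squeeze=False)
    cmap = plt.get_cmap("tab10")
    for ax, chrom in zip(axes[0], chroms):
        for rnd in rounds_by_chr[chrom]:
            for b in rnd.members:
                shade = int(b.chr1) if b.chr1.isdigit() else sum(map(ord, b.chr1))
                ax.barh(y=rnd.comro, width=b.delta_y, left=b.r_y, height=0.6,
                        color=cmap(shade % 10), edgecolor="black",
                        linewidth=0.4)
                ax.text(b.r_y + b.delta_y / 2, rnd.comro, b.chr1,
                        ha="center", va="center", fontsize=6)
        ax.set_xlim(0, ref_lens.get(chrom, 1))
        ax.invert_yaxis()
        ax.set_title(f"reference chr {chrom}", fontsize=9)
        ax.set_xlabel("reference rank")
        ax.set_ylabel("round")
        ax.yaxis.get_major_locator().set_params(integer=True)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
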