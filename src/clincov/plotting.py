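"""Two-panel gene coverage figures.

Upper panel: per-base depth across the whole gene span (exons and introns),
x-axis in genomic coordinates. Lower panel: exon coverage only, with each
exon allocated horizontal width proportional to its length (subject to a
minimum visible width so many-exon genes stay legible), boundaries marked,
and genomic start positions as tick labels. Pathogenic SNV loci are drawn as
dots at (locus, depth) — germline red, somatic dark blue — and exons whose
minimum depth falls below the threshold are filled red.

All semantic content lives in :class:`GeneFigureSpec`, built before any
rendering, so tests assert on coordinates and flags rather than pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .genecov import GeneCoverageReport
from .io import VariantClass

DEFAULT_COLORS = {
    "exon": "lightblue",
    "flagged": "red",
    "germline": "red",
    "somatic": "darkblue",
    "threshold": "dimgray",
    "upper": "lightblue",
}

#: Spans longer than this are max-pooled in the upper panel; max-pooling
#: preserves every sub-threshold dip a per-base trace would show.
MAX_UPPER_POINTS = 200_000


@dataclass(frozen=True)
class ExonPanel:
    exon_index: int
    start: int           # genomic
    end: int
    x0: float            # plot coordinates in the lower panel
    x1: float
    segments: tuple      # (genomic start, genomic end, depth) per covered run
    flagged: bool

    def to_plot_x(self, pos0: int) -> float:
        frac = (pos0 - self.start) / (self.end - self.start)
        return self.x0 + frac * (self.x1 - self.x0)


@dataclass(frozen=True)
class SNVDot:
    variant_class: VariantClass
    pos0: int
    depth: int
    lower_x: float | None  # None when the locus is intronic


@dataclass
class GeneFigureSpec:
    """Pre-render description of the figure; carries all semantics."""

    gene: str
    chrom: str
    span: tuple[int, int]
    threshold: int
    upper_x: np.ndarray
    upper_depth: np.ndarray
    exons: list[ExonPanel]
    dots: list[SNVDot]
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    @property
    def red_exon_segments(self) -> list[tuple[int, float, float]]:
        return [(e.exon_index, e.x0, e.x1) for e in self.exons if e.flagged]


def build_figure_spec(
    report: GeneCoverageReport,
    colors: dict | None = None,
    max_upper_points: int = MAX_UPPER_POINTS,
) -> GeneFigureSpec:
    """Derive the figure spec from a gene report and its embedded profile."""
    profile = report.profile
    depth = profile.depths
    x = np.arange(profile.span_start, profile.span_end)
    if depth.size > max_upper_points:
        pool = math.ceil(depth.size / max_upper_points)
        starts = np.arange(0, depth.size, pool)
        depth = np.maximum.reduceat(depth, starts)
        x = x[starts]

    total_len = sum(r.end - r.start for r in report.exon_rows)
    min_w = 0.01 * total_len  # minimum visible width per exon
    gap = 0.005 * total_len
    panels: list[ExonPanel] = []
    cursor = 0.0
    for row, segs in zip(report.exon_rows, profile.exon_segments):
        w = max(row.end - row.start, min_w)
        panels.append(
            ExonPanel(
                row.exon_index,
                row.start,
                row.end,
                cursor,
                cursor + w,
                tuple((s.start, s.end, s.depth) for s in segs),
                row.flagged,
            )
        )
        cursor += w + gap

    dots = []
    for snv in report.snv_rows:
        lower_x = next(
            (p.to_plot_x(snv.pos0) for p in panels if p.start <= snv.pos0 < p.end),
            None,
        )
        dots.append(SNVDot(snv.variant_class, snv.pos0, snv.depth, lower_x))

    merged = dict(DEFAULT_COLORS)
    if colors:
        merged.update(colors)
    return GeneFigureSpec(
        report.gene,
        report.chrom,
        report.gene_span,
        report.threshold,
        x,
        depth,
        panels,
        dots,
        merged,
    )


def render_gene_figure(
    report: GeneCoverageReport,
    out_path: str | Path,
    colors: dict | None = None,
    dpi: int = 120,
) -> Path:
    """Render the two-panel figure to a PNG; deterministic for fixed input."""
    spec = build_figure_spec(report, colors=colors)
    out_path = Path(out_path)

    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(12, 7), constrained_layout=True
    )
    c = spec.colors

    ax_top.fill_between(spec.upper_x, spec.upper_depth, step="post",
                        color=c["upper"], linewidth=0)
    ax_top.axhline(spec.threshold, color=c["threshold"], linestyle="--",
                   linewidth=1, label=f"threshold {spec.threshold}x")
    for vc in (VariantClass.GERMLINE, VariantClass.SOMATIC):
        pts = [(d.pos0, d.depth) for d in spec.dots if d.variant_class == vc]
        if pts:
            xs, ys = zip(*pts)
            ax_top.scatter(xs, ys, s=18, color=c[vc.value], zorder=3,
                           label=f"{vc.value} SNV")
    ax_top.set_xlim(spec.span)
    ax_top.set_ylim(bottom=0)
    ax_top.set_xlabel(f"genomic locus ({spec.chrom})")
    ax_top.set_ylabel("depth")
    ax_top.set_title(f"{spec.gene} coverage (gene span incl. introns)")
    ax_top.legend(loc="upper right", fontsize=8)

    ticks, labels = [], []
    for panel in spec.exons:
        fill = c["flagged"] if panel.flagged else c["exon"]
        # one step-filled trace per exon, not one artist per segment
        xs = [panel.x0]
        ys = [0]
        for gs, ge, depth in panel.segments:
            # step="post": depth holds from gs to ge, then drops to 0
            xs += [panel.to_plot_x(gs), panel.to_plot_x(ge)]
            ys += [depth, 0]
        xs.append(panel.x1)
        ys.append(0)
        ax_bot.fill_between(xs, ys, color=fill, linewidth=0, step="post")
        if panel.flagged and not panel.segments:
            # fully uncovered exon: draw a thin red marker at depth 0
            ax_bot.fill_between([panel.x0, panel.x1],
                                [spec.threshold * 0.02] * 2,
                                color=fill, linewidth=0)
        ax_bot.axvline(panel.x0, color="gray", linewidth=0.4)
        ax_bot.axvline(panel.x1, color="gray", linewidth=0.4)
        ticks.append((panel.x0 + panel.x1) / 2)
        labels.append(f"{panel.exon_index}\n{panel.start}")
    for dot in spec.dots:
        if dot.lower_x is not None:
            ax_bot.scatter([dot.lower_x], [dot.depth], s=18,
                           color=c[dot.variant_class.value], zorder=3)
    ax_bot.axhline(spec.threshold, color=c["threshold"], linestyle="--",
                   linewidth=1)
    ax_bot.set_xticks(ticks)
    ax_bot.set_xticklabels(labels, fontsize=max(4, 8 - len(spec.exons) // 8))
    ax_bot.set_ylim(bottom=0)
    ax_bot.set_xlabel("exon (index, genomic start)")
    ax_bot.set_ylabel("depth")
    ax_bot.set_title(f"{spec.gene} exon coverage")

    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)
    return out_path
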