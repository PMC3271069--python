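"""Pie-chart and heatmap rendering shared by all tools.

Rendering is a derived view: every number shown here is produced by the
compute modules and written to text first; images never feed back into
the pipeline. SVG is the canonical output format; PNG is selected by
file extension.

Palettes follow the suite's conventions: chemical-shift region pies run
red (upfield) to green (downfield); correlation heatmaps run blue (-1)
through white (0) to red (+1) with sub-cutoff entries blanked white and
undefined entries grey; categorical pies cycle a qualitative palette.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .hetmap import CorrelationMap

__all__ = ["RenderSpec", "render_pie", "render_heatmap", "shift_palette"]

logger = logging.getLogger("ecomics")

PALETTES = ("shift_red_green", "corr_blue_red", "categorical")

_SHIFT_CMAP = LinearSegmentedColormap.from_list(
    "shift_red_green", ["#cc2222", "#ccaa22", "#22aa22"]
)


@dataclass
class RenderSpec:
    """How to draw one figure: palette, title and legend entries."""

    palette: str = "categorical"
    title: str = ""
    legend: bool = True
    palette_positions: Sequence[float] | None = None  # per-slice 0..1, gradient palettes

    def __post_init__(self) -> None:
        if self.palette not in PALETTES:
            raise ValueError(f"unknown palette {self.palette!r}; choose from {PALETTES}")


def shift_palette(positions: Sequence[float]) -> list[tuple[float, float, float, float]]:
    """Red(0, upfield) -> green(1, downfield) colors for region positions."""
    return [_SHIFT_CMAP(float(p)) for p in positions]


def render_pie(
    fractions: Mapping[str, float], spec: RenderSpec, path: str | Path
) -> Path:
    """Render label -> fraction slices as a pie chart (SVG or PNG).

    Fractions must be nonnegative and sum to at most 1 (+1e-9); only
    nonzero labels get slices. All-zero input produces a placeholder
    "empty" figure and logs a warning instead of failing.
    """
    vals = np.array([float(v) for v in fractions.values()])
    if np.any(vals < 0):
        raise ValueError("pie fractions must be nonnegative")
    if vals.sum() > 1 + 1e-9:
        raise ValueError(f"pie fractions sum to {vals.sum():g} > 1")
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    try:
        keep = [(k, v) for k, v in fractions.items() if v > 0]
        if not keep:
            logger.warning("all-zero fractions; rendering an empty placeholder pie")
            ax.text(0.5, 0.5, "empty", ha="center", va="center", fontsize=16)
            ax.set_axis_off()
        else:
            labels = [k for k, _ in keep]
            sizes = [v for _, v in keep]
            if spec.palette == "shift_red_green":
                if spec.palette_positions is not None:
                    pos = {
                        k: p
                        for (k, _), p in zip(fractions.items(), spec.palette_positions)
                    }
                    colors = shift_palette([pos[k] for k in labels])
                else:
                    colors = shift_palette(np.linspace(0, 1, len(labels)))
            elif spec.palette == "corr_blue_red":
                colors = [plt.get_cmap("bwr")(x) for x in np.linspace(0.05, 0.95, len(labels))]
            else:
                cyc = plt.get_cmap("tab20").colors
                colors = [cyc[i % len(cyc)] for i in range(len(labels))]
            wedges, _ = ax.pie(
                sizes,
                colors=colors,
                normalize=False,
                startangle=90,
                counterclock=False,
                wedgeprops={"linewidth": 0.5, "edgecolor": "white"},
            )
            if spec.legend:
                ax.legend(
                    wedges,
                    labels,
                    loc="center left",
                    bbox_to_anchor=(1.0, 0.5),
                    fontsize=7,
                    frameon=False,
                )
        if spec.title:
            ax.set_title(spec.title)
        fig.savefig(path, bbox_inches="tight")
    finally:
        plt.close(fig)
    return path


def render_heatmap(
    cmap: CorrelationMap, cutoff: float = 0.0, path: str | Path = "hetmap.svg", title: str = ""
) -> Path:
    """Render a correlation map: blue(-1) -> white(0) -> red(+1).

    Entries with |r| <= cutoff are blanked white, undefined (NaN)
    entries are grey, and each input block gets a colored bar along both
    margins so within- and between-block regions are readable.
    """
    path = Path(path)
    shown = cmap.values.copy()
    if cutoff > 0:
        shown[np.abs(shown) <= cutoff] = 0.0
    masked = np.ma.masked_invalid(shown)
    palette = plt.get_cmap("bwr").copy()
    palette.set_bad("#bbbbbb")

    fig, ax = plt.subplots(figsize=(6, 5))
    try:
        im = ax.imshow(masked, cmap=palette, vmin=-1.0, vmax=1.0, interpolation="nearest")
        fig.colorbar(im, ax=ax, shrink=0.8, label="r")
        block_colors = plt.get_cmap("tab10").colors
        bar = 0.6
        for bi, (label, start, stop) in enumerate(cmap.blocks):
            color = block_colors[bi % len(block_colors)]
            ax.add_patch(
                plt.Rectangle(
                    (-1.5 - bar, start - 0.5), bar, stop - start, color=color, clip_on=False
                )
            )
            ax.add_patch(
                plt.Rectangle(
                    (start - 0.5, -1.5 - bar), stop - start, bar, color=color, clip_on=False
                )
            )
            mid = (start + stop) / 2 - 0.5
            ax.text(-2.2 - bar, mid, label, ha="right", va="center", fontsize=7)
        ax.set_xticks([])
        ax.set_yticks([])
        if title:
            ax.set_title(title)
        fig.savefig(path, bbox_inches="tight")
    finally:
        plt.close(fig)
    return path
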