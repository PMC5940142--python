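"""Plot helpers: similarity heatmaps and evaluation-plane projections.

Heatmaps use perceptually uniform colormaps with per-map color scales;
projection plots render each surface into the (xw, xn) plane with a
per-surface min/max scale, so every surface's own amplitude spans its
colormap.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .surfaces import DEFAULT_GRID, EvaluationGrid, surface_grid

__all__ = ["score_heatmap", "projection_plot", "scan_manhattan"]


def score_heatmap(scores: pd.DataFrame, path, title: str = "",
                  cmap: str = "viridis") -> None:
    """One heatmap per score matrix: rows are (e, s) pairs, columns
    ring-ordered mesh points; the color scale is specific to this map."""
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.12 * scores.shape[1]), max(3.0, 0.3 * scores.shape[0]))
    )
    sns.heatmap(scores, ax=ax, cmap=cmap, center=None,
                cbar_kws={"shrink": 0.8}, xticklabels=max(1, scores.shape[1] // 30))
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def projection_plot(surfaces: dict[str, object], path,
                    grid: EvaluationGrid = DEFAULT_GRID, ncols: int = 4,
                    cmap: str = "viridis") -> None:
    """Project each surface into the evaluation plane, one panel each,
    color scaled to that surface's own min/max."""
    labels = list(surfaces)
    nrows = (len(labels) + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.2 * nrows),
                             squeeze=False)
    extent = (*grid.water_interval, *grid.nitrogen_interval)
    for ax, label in zip(axes.flat, labels):
        z = surface_grid(surfaces[label], grid)
        im = ax.imshow(z.T, origin="lower", aspect="auto", extent=extent, cmap=cmap)
        ax.set_title(label, fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.85)
    for ax in axes.flat[len(labels):]:
        ax.set_visible(False)
    fig.supxlabel("water (recentred)")
    fig.supylabel("nitrogen (recentred)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scan_manhattan(markers: pd.DataFrame, path, alpha_line: float | None = None) -> None:
    """-log10 p along the marker order, colored by chromosome."""
    fig, ax = plt.subplots(figsize=(8, 3))
    for chrom, grp in markers.groupby("chromosome", sort=True):
        p = np.maximum(grp["smoothed_p"].to_numpy(float), 1e-300)
        ax.scatter(grp["order"], -np.log10(p), s=8, label=f"chr{chrom}")
    if alpha_line is not None:
        ax.axhline(-np.log10(alpha_line), color="grey", ls="--", lw=0.8)
    ax.set_xlabel("marker order")
    ax.set_ylabel(r"$-\log_{10}$ smoothed p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
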