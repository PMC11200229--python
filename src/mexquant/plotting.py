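"""Figure export: cluster heatmaps, UMAP embeddings, amount histograms, maps.

Thin matplotlib wrappers used by the CLI and the examples; every function
writes a PNG and returns the path. Rendering is deliberately plain — the
quantitative outputs live in the CSV/TIFF files these figures accompany.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = [
    "save_heatmap_png",
    "save_umap_png",
    "save_histogram_png",
    "save_label_map_png",
    "save_amount_map_png",
]


def save_heatmap_png(heat: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Cluster × channel mean-intensity heatmap."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(heat.columns), 1 + 0.4 * len(heat)))
    im = ax.imshow(heat.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(heat.columns)), heat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(heat)), [f"cluster {i}" for i in heat.index])
    ax.set_title(title or "per-cluster mean scaled intensity")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_umap_png(
    coords: np.ndarray, labels: np.ndarray | None, path: str | Path
) -> Path:
    """2-D embedding scatter, colored by cluster when labels are given."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    c = labels if labels is not None else "steelblue"
    s = ax.scatter(coords[:, 0], coords[:, 1], c=c, s=8, cmap="tab10")
    if labels is not None:
        ax.legend(*s.legend_elements(), title="cluster", loc="best", fontsize=8)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_histogram_png(
    hist: dict, path: str | Path, xlabel: str = "amount (fg/cell)"
) -> Path:
    """Histogram from :func:`mexquant.calibration.amount_histogram` output."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    edges = hist["bin_edges"]
    ax.bar(edges[:-1], hist["counts"], width=np.diff(edges), align="edge",
           color="steelblue", edgecolor="white")
    if hist["n"]:
        ax.axvline(hist["mean"], color="crimson", linestyle="--",
                   label=f"mean {hist['mean']:.2f} ± {hist['sd']:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("cells")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_label_map_png(labels: np.ndarray, path: str | Path) -> Path:
    """Categorical raster (cluster overlay / pixel classes); 0 = background."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 5))
    masked = np.ma.masked_equal(labels, 0)
    ax.imshow(masked, cmap="tab10", interpolation="nearest")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def save_amount_map_png(
    amounts: np.ndarray, path: str | Path, unit: str = "fg/pixel"
) -> Path:
    """Continuous concentration-coded map with a colorbar."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(amounts, cmap="inferno", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8, label=unit)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
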