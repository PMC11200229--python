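"""Pixel-level analysis: k-means segmentation of elemental maps, per-cluster
quantified amounts, and Spearman correlation heatmaps.

Where single-cell analysis needs staining and segmentation, pixel analysis
works directly on the per-pixel count table — useful e.g. to compare labeled
and unlabeled consecutive sections, or when no membrane marker is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .calibration import CalibrationCurve
from .types import PixelTable

__all__ = ["PixelClusterMap", "kmeans_pixels", "cluster_amounts", "spearman_heatmap"]


@dataclass
class PixelClusterMap:
    """Per-pixel cluster assignment plus per-cluster channel means.

    ``labels`` is the (height, width) raster of cluster ids 0..k−1;
    ``cluster_means`` is the k × C table of mean counts per cluster. Cluster
    ids are ordered by ascending mean of ``order_channel`` so replicate runs
    align (raw k-means labels are arbitrary).
    """

    labels: np.ndarray
    k: int
    cluster_means: pd.DataFrame
    order_channel: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


def kmeans_pixels(
    pixels: PixelTable,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = True,
    order_channel: str | None = None,
) -> PixelClusterMap:
    """Cluster pixels into k groups by their multichannel count vectors.

    k-means++ initialization, best of ``n_init`` runs by inertia, fixed seed.
    Channels are standardized (z-score) before clustering by default so
    high-count channels do not dominate; the reported cluster means are
    always in raw counts. Cluster ids are sorted by ascending mean of
    ``order_channel`` (default: first channel).
    """
    x = pixels.counts.to_numpy(dtype=np.float64)
    n_distinct = len(np.unique(x, axis=0))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct pixel vectors"
        )
    xs = x
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        xs = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
    raw_labels = km.fit_predict(xs)

    order_channel = order_channel or pixels.isotopes[0]
    means = pd.DataFrame(
        [x[raw_labels == i].mean(axis=0) for i in range(k)],
        columns=pixels.isotopes,
    )
    order = np.argsort(means[order_channel].to_numpy(), kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    labels = remap[raw_labels].reshape(pixels.height, pixels.width)
    means = means.iloc[order].reset_index(drop=True)
    means.index.name = "cluster"
    return PixelClusterMap(
        labels=labels, k=k, cluster_means=means, order_channel=order_channel
    )


def cluster_amounts(
    maps: PixelClusterMap | list[PixelClusterMap],
    curve: CalibrationCurve,
    channel: str | None = None,
    subtract_intercept: bool = True,
) -> pd.DataFrame:
    """Per-cluster mean quantified amount (fg/pixel), replicates as mean ± sd.

    Accepts a single cluster map or a list of replicate maps (consecutive
    sections / repeated measurements); replicates are aggregated per cluster
    id as mean and standard deviation over the replicate means.
    """
    if isinstance(maps, PixelClusterMap):
        maps = [maps]
    channel = channel or curve.element
    ks = {m.k for m in maps}
    if len(ks) != 1:
        raise ValueError(f"replicate maps disagree on k: {sorted(ks)}")
    k = ks.pop()
    per_rep = np.empty((len(maps), k))
    for r, m in enumerate(maps):
        if channel not in m.cluster_means.columns:
            raise KeyError(f"channel {channel!r} not in cluster means")
        per_rep[r] = curve.counts_to_fg(
            m.cluster_means[channel].to_numpy(), subtract_intercept=subtract_intercept
        )
    out = pd.DataFrame(
        {
            "cluster": np.arange(k),
            "mean_fg_per_px": per_rep.mean(axis=0),
            "sd_fg_per_px": per_rep.std(axis=0, ddof=1) if len(maps) > 1 else 0.0,
            "n_replicates": len(maps),
        }
    )
    return out


def spearman_heatmap(
    pixels: PixelTable, channels: list[str] | None = None
) -> pd.DataFrame:
    """C × C Spearman rank-correlation matrix over pixels.

    Symmetric with unit diagonal; invariant under any strictly monotone
    per-channel transform, which makes it robust to the nonlinear response
    differences between elements.
    """
    channels = channels or pixels.isotopes
    if len(channels) < 2:
        raise ValueError("need at least 2 channels")
    rho = pixels.counts[channels].corr(method="spearman")
    np.fill_diagonal(rho.to_numpy(), 1.0)
    return rho
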