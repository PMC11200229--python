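"""Single-cell phenotyping: normalize → outlier-filter → scale → cluster,
plus UMAP embedding, cluster heatmaps, spatial projections and per-cluster
statistics.

The pipeline order is fixed and recorded on the feature matrix itself
(``state`` transitions raw → size-normalized → scaled), and every stochastic
step takes an explicit seed, so a run is reproducible bit-exactly.

Clustering is the Phenograph construction: a k-nearest-neighbor graph on the
scaled features (Euclidean), edges reweighted by the Jaccard overlap of the
endpoints' neighbor sets, then Leiden community detection (RB-configuration
modularity). Cells in a dense, internally well-connected neighborhood end up
in one community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import amount_col
from .types import CELL_ID, SegmentationMask, mean_col, total_col

__all__ = [
    "FeatureMatrix",
    "ClusterResult",
    "size_normalize",
    "filter_outliers",
    "scale_features",
    "cluster_phenograph",
    "embed_umap",
    "cluster_heatmap",
    "project_clusters",
    "project_amounts",
    "compare_clusters",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Cells × channels feature matrix with an explicit normalization state.

    ``values`` is indexed by cell id; ``state`` records the preparation
    history (``raw``, ``size-normalized``, ``scaled`` and combinations).
    """

    values: pd.DataFrame
    state: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_cells(self) -> int:
        return len(self.values)

    @property
    def channels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cell_ids(self) -> np.ndarray:
        return self.values.index.to_numpy()

    def with_values(self, values: pd.DataFrame, step: str) -> "FeatureMatrix":
        return replace(self, values=values, state=self.state + (step,))


@dataclass(frozen=True)
class ClusterResult:
    """Community labels per cell plus the parameters that produced them."""

    labels: np.ndarray  # cluster id per cell, 0..K-1
    k: int
    quality: float  # Leiden partition quality (modularity-like)
    k_neighbors: int
    resolution: float
    seed: int
    cell_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.k < 1 or len(self.labels) == 0:
            raise ValueError("cluster result must label at least one cell")
        if set(np.unique(self.labels)) != set(range(self.k)):
            raise ValueError("labels must cover 0..K-1")


def size_normalize(
    cells: pd.DataFrame,
    pixel_size_um: float = 1.0,
    channels: list[str] | None = None,
) -> FeatureMatrix:
    """Divide integrated intensities by cell area in µm² ("real world" size).

    Removes cell-size effects before clustering: a big and a small cell with
    the same element density get the same feature value. ``channels`` defaults
    to every isotope with a ``*_total`` column.
    """
    from .types import isotopes_in_table

    channels = channels or isotopes_in_table(cells)
    if not channels:
        raise ValueError("no channels to normalize")
    area_um2 = cells["area_px"].to_numpy(dtype=np.float64) * pixel_size_um**2
    data = {
        ch: cells[total_col(ch)].to_numpy(dtype=np.float64) / area_um2
        for ch in channels
    }
    values = pd.DataFrame(data, index=pd.Index(cells[CELL_ID], name=CELL_ID))
    return FeatureMatrix(values=values, state=("raw", "size-normalized"))


def filter_outliers(fm: FeatureMatrix, upper_pct: float = 99.5) -> FeatureMatrix:
    """Remove cells with any channel value above that channel's percentile.

    Intensity outliers (residual hot pixels, debris) distort scaling and
    clustering; removal, not winsorization, keeps the matrix consistent with
    the cell table. Removed cell ids are recorded in ``fm.state`` metadata
    and logged.
    """
    if not 0 < upper_pct <= 100:
        raise ValueError("upper_pct must be in (0, 100]")
    if upper_pct == 100:
        return fm.with_values(fm.values.copy(), "outlier-filtered[none]")
    cutoff = fm.values.quantile(upper_pct / 100.0)
    keep = (fm.values <= cutoff).all(axis=1)
    removed = fm.values.index[~keep].tolist()
    if removed:
        warnings.warn(f"outlier filter removed {len(removed)} cells", stacklevel=2)
    return fm.with_values(fm.values.loc[keep], f"outlier-filtered[{len(removed)}]")


def scale_features(fm: FeatureMatrix, method: str = "minmax") -> FeatureMatrix:
    """Per-channel scaling for clustering: min–max to [0,1] or z-score.

    Constant channels map to 0 with a warning (they carry no phenotype
    information but would otherwise produce NaNs).
    """
    vals = fm.values.copy()
    for ch in vals.columns:
        col = vals[ch].to_numpy(dtype=np.float64)
        spread = np.ptp(col) if method == "minmax" else col.std(ddof=0)
        if spread == 0:
            warnings.warn(f"channel {ch} is constant; scaled to all zeros")
            vals[ch] = 0.0
        elif method == "minmax":
            vals[ch] = (col - col.min()) / spread
        elif method == "zscore":
            vals[ch] = (col - col.mean()) / spread
        else:
            raise ValueError(f"unknown scaling method {method!r}")
    return fm.with_values(vals, f"scaled[{method}]")


def _jaccard_knn_graph(x: np.ndarray, k_neighbors: int):
    """kNN graph with Jaccard-of-neighborhoods edge weights (igraph)."""
    import igraph as ig
    from sklearn.neighbors import NearestNeighbors

    n = x.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x)
    _, idx = nn.kneighbors(x)
    neigh = [set(row) | {i} for i, row in enumerate(idx)]  # closed neighborhoods
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w > 0:
                edges.append(key)
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_phenograph(
    fm: FeatureMatrix,
    k_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """Phenograph-style clustering: Jaccard-weighted kNN graph + Leiden.

    Deterministic for a fixed seed. Requires more cells than ``k_neighbors``.
    """
    import leidenalg

    n = fm.n_cells
    if n <= k_neighbors:
        raise ValueError(
            f"n cells ({n}) must exceed k_neighbors ({k_neighbors}); "
            "use a smaller k"
        )
    x = fm.values.to_numpy(dtype=np.float64)
    g = _jaccard_knn_graph(x, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership, dtype=np.int64)
    # relabel by descending cluster size so ids are stable across runs
    order = np.argsort(-np.bincount(labels), kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[labels]
    return ClusterResult(
        labels=labels,
        k=int(labels.max()) + 1,
        quality=float(part.quality()),
        k_neighbors=k_neighbors,
        resolution=resolution,
        seed=seed,
        cell_ids=fm.cell_ids,
    )


def embed_umap(fm: FeatureMatrix, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP embedding of the feature matrix, for visualization only.

    One (x, y) point per cell; deterministic for a fixed seed.
    """
    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, max(fm.n_cells - 1, 2)),
        random_state=seed,
    )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; intended
        warnings.simplefilter("ignore")
        return np.asarray(reducer.fit_transform(fm.values.to_numpy()))


def cluster_heatmap(fm: FeatureMatrix, clusters: ClusterResult) -> pd.DataFrame:
    """K × C matrix of per-cluster mean (scaled) channel intensities.

    Row k is the mean over the cells with label k — the cluster's expression
    profile used to characterize phenotypes.
    """
    if len(clusters.labels) != fm.n_cells:
        raise ValueError("cluster labels and feature matrix disagree on cell count")
    df = fm.values.copy()
    df["_cluster"] = clusters.labels
    out = df.groupby("_cluster").mean()
    out.index.name = "cluster"
    return out


def project_clusters(mask: SegmentationMask, clusters: ClusterResult) -> np.ndarray:
    """Paint each cell's pixels with its cluster id + 1 (background 0)."""
    lut = np.zeros(mask.n_objects + 1, dtype=np.int32)
    for cid, lab in zip(clusters.cell_ids, clusters.labels):
        lut[int(cid)] = int(lab) + 1
    return lut[mask.labels]


def project_amounts(
    mask: SegmentationMask, quantified: pd.DataFrame, channel: str
) -> np.ndarray:
    """Paint each cell's pixels with its quantified amount (fg); background 0."""
    col = amount_col(channel)
    if col not in quantified.columns:
        raise KeyError(f"no quantified column {col}")
    lut = np.zeros(mask.n_objects + 1, dtype=np.float64)
    for cid, amt in zip(quantified[CELL_ID], quantified[col]):
        lut[int(cid)] = float(amt)
    return lut[mask.labels]


def compare_clusters(
    quantified: pd.DataFrame,
    clusters: ClusterResult,
    channel: str,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Pairwise two-sided Mann–Whitney U on per-cluster amounts.

    Exact null distribution when min(n₁, n₂) ≤ 8 and there are no ties,
    normal approximation with tie correction otherwise. P-values are
    Bonferroni-adjusted over the K·(K−1)/2 pairs. Every cluster must have at
    least 3 cells.
    """
    col = amount_col(channel)
    if col not in quantified.columns:
        col = total_col(channel)
        if col not in quantified.columns:
            raise KeyError(f"no amount or intensity column for channel {channel!r}")
    labels = np.asarray(clusters.labels)
    values = quantified[col].to_numpy()
    if len(values) != len(labels):
        raise ValueError("quantified table and cluster labels disagree on length")
    ids = np.unique(labels)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters to compare")
    groups = {i: values[labels == i] for i in ids}
    for i, g in groups.items():
        if len(g) < 3:
            raise ValueError(f"cluster {i} has fewer than 3 cells")
    n_pairs = len(ids) * (len(ids) - 1) // 2
    rows = []
    for a_i, a in enumerate(ids):
        for b in ids[a_i + 1 :]:
            x, y = groups[a], groups[b]
            ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
            method = "exact" if (min(len(x), len(y)) <= 8 and not ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            p_adj = min(res.pvalue * n_pairs, 1.0) if adjust == "bonferroni" else res.pvalue
            rows.append(
                {
                    "cluster_a": int(a),
                    "cluster_b": int(b),
                    "u_statistic": float(res.statistic),
                    "p_value": float(res.pvalue),
                    "p_adjusted": float(p_adj),
                    "method": method,
                }
            )
    return pd.DataFrame(rows)
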