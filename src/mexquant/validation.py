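"""Self-validation on ground-truthed synthetic data.

Each report runs the relevant slice of the pipeline on data from
:mod:`mexquant.synthetic` and measures recovery against the generator's
ground truth — parameter recovery, filter selectivity, calibration accuracy,
detection-limit calibration and clustering fidelity. They are the package's
built-in way to check, on any machine, that the full chain behaves as the
measurement model predicts.
"""

from __future__ import annotations

import warnings

import numpy as np

from .calibration import (
    DropletStandard,
    currie_false_positive_rate,
    fit_calibration,
    integrate_droplet_windows,
)
from .phenotyping import (
    cluster_phenograph,
    filter_outliers,
    scale_features,
    size_normalize,
)
from .pixels import kmeans_pixels, spearman_heatmap
from .preprocess import HotPixelParams, median_filter, remove_hot_pixels, stack_channels
from .segmentation import (
    extract_features,
    filter_border_objects,
    filter_by_size,
    watershed_segment,
)
from .synthetic import TissueSimulationConfig, match_cells, simulate_droplets, simulate_tissue
from .types import ImageStack, PixelTable, total_col

__all__ = [
    "tissue_recovery_report",
    "hot_pixel_report",
    "calibration_report",
    "lod_report",
    "pixel_report",
]


def tissue_recovery_report(
    seed: int = 0, cfg: TissueSimulationConfig | None = None
) -> dict:
    """Full-chain parameter recovery on default-condition synthetic tissue.

    simulate → hot-pixel removal → watershed segmentation → object filters →
    feature extraction → quantification (true slope) → phenotyping, measured
    against the generator's truth. Returns population-mean relative error,
    median per-cell relative error, object recall and clustering ARI.
    """
    from sklearn.metrics import adjusted_rand_score

    cfg = cfg or TissueSimulationConfig()
    stack, truth = simulate_tissue(cfg, seed=seed)

    metal = remove_hot_pixels(stack.channel(cfg.metal_isotope), HotPixelParams())
    cleaned = ImageStack(
        [metal if c.isotope == cfg.metal_isotope else c for c in stack.channels],
        panel=stack.panel,
    )
    seg_stack = stack_channels(
        median_filter(stack.channel(cfg.nucleus_isotope), 1),
        median_filter(stack.channel(cfg.membrane_isotope), 1),
    )
    mask = filter_by_size(
        filter_border_objects(watershed_segment(seg_stack, 10.0)), 10, 10_000
    )
    cells = extract_features(mask, cleaned)
    match = match_cells(mask, truth.mask)

    hit = match[match.truth_id > 0]
    det = cells.set_index("cell_id").loc[hit.detected_id]
    tru = truth.cells.set_index("cell_id").loc[hit.truth_id]
    est_fg = det[total_col(cfg.metal_isotope)].to_numpy() / cfg.calibration_slope
    true_fg = tru["amount_fg"].to_numpy()
    rel_err = np.abs(est_fg - true_fg) / true_fg

    marker_channels = sorted(
        {iso for ph in cfg.phenotypes for iso in ph.channel_means}
    )
    fm = size_normalize(cells, channels=marker_channels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fm = scale_features(filter_outliers(fm))
    clusters = cluster_phenograph(fm, k_neighbors=30, resolution=1.0, seed=seed)
    lookup = match.set_index("detected_id")["truth_id"]
    true_pheno = truth.cells.set_index("cell_id")["phenotype"]
    ari = adjusted_rand_score(
        true_pheno.loc[lookup.loc[fm.cell_ids]].to_numpy(), clusters.labels
    )

    return {
        "n_cells_true": len(truth.cells),
        "n_cells_detected": mask.n_objects,
        "object_recall": float(hit.truth_id.nunique() / len(truth.cells)),
        "population_mean_true_fg": float(true_fg.mean()),
        "population_mean_recovered_fg": float(est_fg.mean()),
        "population_mean_rel_err": float(
            abs(est_fg.mean() - true_fg.mean()) / true_fg.mean()
        ),
        "median_cell_rel_err": float(np.median(rel_err)),
        "n_phenotype_clusters": clusters.k,
        "phenotype_ari": float(ari),
    }


def hot_pixel_report(seed: int = 0) -> dict:
    """Spike-removal selectivity on the default tissue's metal channel."""
    cfg = TissueSimulationConfig()
    stack, truth = simulate_tissue(cfg, seed=seed)
    metal = stack.channel(cfg.metal_isotope)
    once = remove_hot_pixels(metal, HotPixelParams())
    twice = remove_hot_pixels(once, HotPixelParams())
    changed = set(map(tuple, np.argwhere(once.pixels != metal.pixels)))
    spikes = set(map(tuple, truth.hot_pixels[cfg.metal_isotope]))
    return {
        "n_spikes": len(spikes),
        "spikes_removed_frac": len(spikes & changed) / len(spikes),
        "non_spike_alterations": len(changed - spikes),
        "idempotent": bool(np.array_equal(twice.pixels, once.pixels)),
    }


def calibration_report(seed: int = 0, n_reps: int = 100) -> dict:
    """Noiseless exactness plus Poisson-noise slope coverage.

    The noiseless branch fits an exact line through a blank + 5 standards;
    the stochastic branch refits ``n_reps`` Poisson-noisy droplet series at
    slope 50 counts/fg and reports how often the true slope falls within
    3 counting-statistics SEs, and the relative slope error of one full
    simulated-image recovery.
    """
    amounts = np.array([0.0, 2.0, 5.0, 10.0, 20.0, 50.0])
    exact = fit_calibration(
        [DropletStandard("59Co", a / 0.4, 400.0, 50.0 * a) for a in amounts]
    )
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        counts = rng.poisson(50.0 * amounts)
        fit = fit_calibration(
            [
                DropletStandard("59Co", a / 0.4, 400.0, float(c))
                for a, c in zip(amounts, counts)
            ]
        )
        hits += abs(fit.slope - 50.0) <= 3 * fit.slope_se

    image, std = simulate_droplets(seed=seed, slope=50.0)
    centers = std[["center_row_px", "center_col_px"]].to_numpy()
    window_counts = integrate_droplet_windows(
        image, centers, radius_px=float(std["radius_px"].iloc[0]) + 2
    )
    recovered = fit_calibration(
        [
            DropletStandard("59Co", r.concentration_ug_per_L, r.volume_pL, c)
            for (_, r), c in zip(std.iterrows(), window_counts)
        ]
    )
    return {
        "noiseless_slope_err": abs(exact.slope - 50.0),
        "noiseless_intercept_err": abs(exact.intercept),
        "noiseless_r_squared": exact.r_squared,
        "slope_within_3se_frac": hits / n_reps,
        "image_slope_rel_err": abs(recovered.slope - 50.0) / 50.0,
        "n_reps": n_reps,
    }


def lod_report(seed: int = 0, blank_mean: float = 100.0, n: int = 100_000) -> dict:
    """Monte-Carlo check of the Currie decision threshold at blank mean B."""
    rate = currie_false_positive_rate(blank_mean, n=n, seed=seed)
    return {"blank_mean_counts": blank_mean, "false_positive_rate": rate, "n": n}


def pixel_report(seed: int = 0) -> dict:
    """Two-region k-means recovery and Spearman monotone invariance."""
    img = np.zeros((40, 40))
    img[:, 20:] = 100.0
    table = PixelTable.from_rasters({"59Co": img})
    cmap = kmeans_pixels(table, k=2, seed=seed)
    accuracy = float(np.mean((cmap.labels == 1) == (img == 100.0)))

    rng = np.random.default_rng(seed)
    x = {c: rng.poisson(8, (30, 30)).astype(float) for c in ("a", "b", "c")}
    t1 = PixelTable.from_rasters(x)
    t2 = PixelTable.from_rasters(
        {"a": np.exp(x["a"] / 4), "b": x["b"] ** 3, "c": 5 * x["c"] + 1}
    )
    dev = float(
        np.max(np.abs(spearman_heatmap(t1).to_numpy() - spearman_heatmap(t2).to_numpy()))
    )
    return {"two_region_accuracy": accuracy, "spearman_monotone_max_dev": dev}
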