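"""Cell segmentation, object filtering and per-cell feature extraction.

The native segmenter is a seeded watershed: seeds come from distance-transform
peaks of the smoothed, Otsu-thresholded nucleus channel; regions grow over an
inverted membrane/cytoplasm elevation map, constrained to a foreground mask.
It exists so the pipeline runs end-to-end without external deep-learning
tools; masks produced by any external segmenter (e.g. a pretrained neural
model) can be imported instead and take precedence when supplied.

Object filters mirror the standard single-cell QC steps: drop objects touching
the raster border (truncated cells) and objects outside a plausible size
range. Feature extraction yields one row per retained cell with morphology and
per-isotope integrated/mean counts; intensity is conserved exactly
(sum over cells + background = total image counts).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_triangle
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .types import CELL_ID, ChannelImage, ImageStack, SegmentationMask, mean_col, total_col

__all__ = [
    "watershed_segment",
    "filter_border_objects",
    "filter_by_size",
    "extract_features",
    "DEFAULT_MIN_SIZE_PX",
    "DEFAULT_MAX_SIZE_PX",
]

# bounds bracketing plausible cells at 1 µm/px for ~10 µm diameter cells
DEFAULT_MIN_SIZE_PX = 10
DEFAULT_MAX_SIZE_PX = 10_000


def watershed_segment(
    stack: ImageStack, expected_diameter_um: float = 10.0
) -> SegmentationMask:
    """Segment cells from a 2-channel (membrane, nucleus) stack.

    Parameters
    ----------
    stack
        Exactly two channels ordered (membrane, nucleus), as produced by
        :func:`mexquant.preprocess.stack_channels`.
    expected_diameter_um
        Typical cell diameter; sets the smoothing scale and the minimum seed
        separation (half a diameter).
    """
    if len(stack.channels) != 2:
        raise ValueError(
            f"expected a 2-channel (membrane, nucleus) stack, got "
            f"{len(stack.channels)} channels"
        )
    membrane, nucleus = stack.channels[0], stack.channels[1]
    diam_px = expected_diameter_um / stack.pixel_size_um
    sigma = max(diam_px / 8.0, 0.5)

    nuc = ndimage.gaussian_filter(nucleus.pixels.astype(np.float64), sigma)
    mem = ndimage.gaussian_filter(membrane.pixels.astype(np.float64), sigma)
    combined_raw = nucleus.pixels.astype(np.float64) + membrane.pixels.astype(np.float64)

    if combined_raw.max() <= 0 or np.ptp(combined_raw) == 0:
        warnings.warn("empty foreground: no signal in membrane+nucleus")
        return SegmentationMask(np.zeros(stack.shape, dtype=np.int32))

    # triangle threshold on the unsmoothed sum: robust when most of the
    # raster is background (Otsu lands mid-plateau and halves the masks),
    # and avoids the halo a smoothed image would add around each cell
    foreground = combined_raw > threshold_triangle(combined_raw)
    nuc_fg = nuc > threshold_triangle(nuc) if np.ptp(nuc) > 0 else np.zeros_like(foreground)
    if not foreground.any() or not nuc_fg.any():
        warnings.warn("empty foreground after thresholding; returning 0 objects")
        return SegmentationMask(np.zeros(stack.shape, dtype=np.int32))

    distance = ndimage.distance_transform_edt(nuc_fg)
    min_sep = max(int(round(diam_px / 2.0)), 1)
    peaks = peak_local_max(
        distance, min_distance=min_sep, labels=nuc_fg, exclude_border=False
    )
    seeds = np.zeros(stack.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        warnings.warn("no nucleus seeds found; returning 0 objects")
        return SegmentationMask(seeds)

    elevation = -mem  # cell interiors become basins
    labels = watershed(elevation, markers=seeds, mask=foreground)
    return SegmentationMask(labels)


def filter_border_objects(mask: SegmentationMask) -> SegmentationMask:
    """Remove every object with at least one pixel on the raster border."""
    lab = mask.labels
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border = border[border > 0]
    out = lab.copy()
    out[np.isin(out, border)] = 0
    return SegmentationMask(out)


def filter_by_size(
    mask: SegmentationMask,
    min_px: int = DEFAULT_MIN_SIZE_PX,
    max_px: float = DEFAULT_MAX_SIZE_PX,
) -> SegmentationMask:
    """Remove objects with pixel area outside ``[min_px, max_px]``."""
    lab = mask.labels
    if mask.n_objects == 0:
        return mask
    areas = np.bincount(lab.ravel(), minlength=mask.n_objects + 1)
    bad = np.flatnonzero((areas < min_px) | (areas > max_px))
    bad = bad[bad > 0]
    out = lab.copy()
    out[np.isin(out, bad)] = 0
    return SegmentationMask(out)


def extract_features(mask: SegmentationMask, stack: ImageStack) -> pd.DataFrame:
    """Extract the per-cell feature matrix (cell table).

    One row per labeled object, with columns: ``cell_id``, centroid (px),
    ``area_px``, ``equivalent_diameter_um``, ``eccentricity``, and per isotope
    ``<iso>_total`` (integrated counts, exact sum over the object's pixels)
    and ``<iso>_mean``.
    """
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} != stack shape {stack.shape}")
    lab = mask.labels
    n = mask.n_objects
    ids = np.arange(1, n + 1)

    if n == 0:
        cols = [CELL_ID, "centroid_row_px", "centroid_col_px", "area_px",
                "equivalent_diameter_um", "eccentricity"]
        for iso in stack.isotopes:
            cols += [total_col(iso), mean_col(iso)]
        return pd.DataFrame(columns=cols)

    props = regionprops(lab)
    rows = {
        CELL_ID: ids,
        "centroid_row_px": [p.centroid[0] for p in props],
        "centroid_col_px": [p.centroid[1] for p in props],
        "area_px": np.asarray([p.area for p in props], dtype=np.int64),
        "equivalent_diameter_um": [
            p.equivalent_diameter_area * stack.pixel_size_um for p in props
        ],
        "eccentricity": [p.eccentricity for p in props],
    }
    areas = rows["area_px"]
    for ch in stack.channels:
        # exact integer-preserving sums, not mean*area
        totals = ndimage.sum_labels(ch.pixels, labels=lab, index=ids)
        rows[total_col(ch.isotope)] = totals
        rows[mean_col(ch.isotope)] = totals / areas
    return pd.DataFrame(rows)
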