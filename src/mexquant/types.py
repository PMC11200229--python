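"""Core in-memory containers for elemental image analysis.

Conventions used throughout the package:

* rasters are 2-D numpy arrays, 0-based, row-major, origin at the top-left;
* all geometry is in pixel units and converted to micrometres only through
  ``pixel_size_um`` (1 µm per pixel edge by default, the low-dispersion
  laser-ablation convention);
* channel identity is the isotope string (``"59Co"``, ``"193Ir"``); antibody
  / marker names live in the panel configuration only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChannelImage",
    "ImageStack",
    "SegmentationMask",
    "PixelTable",
    "CELL_ID",
    "total_col",
    "mean_col",
    "isotopes_in_table",
]

#: canonical cell-table column names
CELL_ID = "cell_id"
MORPHOLOGY_COLUMNS = (
    "cell_id",
    "centroid_row_px",
    "centroid_col_px",
    "area_px",
    "equivalent_diameter_um",
    "eccentricity",
)


def total_col(isotope: str) -> str:
    """Cell-table column holding integrated (summed) counts of an isotope."""
    return f"{isotope}_total"


def mean_col(isotope: str) -> str:
    """Cell-table column holding per-pixel mean counts of an isotope."""
    return f"{isotope}_mean"


def isotopes_in_table(table: pd.DataFrame) -> list[str]:
    """Isotope labels present in a cell table (from its ``*_total`` columns)."""
    return [c[: -len("_total")] for c in table.columns if c.endswith("_total")]


@dataclass(frozen=True)
class ChannelImage:
    """A single-isotope count raster with pixel-size metadata.

    Parameters
    ----------
    pixels
        2-D array of non-negative, finite per-pixel counts.
    isotope
        Isotope label, e.g. ``"59Co"``.
    pixel_size_um
        Edge length of one pixel in micrometres (default 1.0).
    """

    pixels: np.ndarray
    isotope: str
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={px.ndim}")
        if not np.issubdtype(px.dtype, np.number):
            raise ValueError(f"raster must be numeric, got dtype {px.dtype}")
        if not np.all(np.isfinite(px)):
            raise ValueError("raster contains non-finite values")
        if px.min() < 0:
            raise ValueError("raster contains negative counts")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "ChannelImage":
        """Copy of this image with a new raster, metadata preserved."""
        return replace(self, pixels=pixels)

    def total(self) -> float:
        return float(self.pixels.sum())


@dataclass
class ImageStack:
    """An ordered list of same-shaped :class:`ChannelImage` plus a panel map.

    ``panel`` maps isotope → marker name (e.g. ``"193Ir" -> "DNA-intercalator"``);
    it is purely descriptive and never used for arithmetic.
    """

    channels: list[ChannelImage]
    panel: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack needs at least one channel")
        shape = self.channels[0].shape
        size = self.channels[0].pixel_size_um
        labels = [c.isotope for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate isotope labels in stack: {labels}")
        for c in self.channels:
            if c.shape != shape:
                raise ValueError(
                    f"channel {c.isotope} shape {c.shape} != stack shape {shape}"
                )
            if c.pixel_size_um != size:
                raise ValueError("channels disagree on pixel size")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape

    @property
    def pixel_size_um(self) -> float:
        return self.channels[0].pixel_size_um

    @property
    def isotopes(self) -> list[str]:
        return [c.isotope for c in self.channels]

    def channel(self, isotope: str) -> ChannelImage:
        for c in self.channels:
            if c.isotope == isotope:
                return c
        raise KeyError(f"isotope {isotope!r} not in stack {self.isotopes}")

    def __contains__(self, isotope: str) -> bool:
        return isotope in self.isotopes

    def as_array(self) -> np.ndarray:
        """(C, H, W) array view of the stack, channel order preserved."""
        return np.stack([c.pixels for c in self.channels])


@dataclass(frozen=True)
class SegmentationMask:
    """Integer-labeled raster: 0 = background, 1..N = cell ids.

    Labels are always relabeled to consecutive ``1..N`` on construction so
    downstream joins have stable ids.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={lab.ndim}")
        if not np.issubdtype(lab.dtype, np.integer):
            if np.any(lab != np.round(lab)):
                raise ValueError("mask contains non-integer values")
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValueError("mask contains negative labels")
        # relabel to consecutive 1..N
        ids = np.unique(lab)
        ids = ids[ids > 0]
        lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
        lut[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
        object.__setattr__(self, "labels", lut[lab])

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(1, self.n_objects + 1)


@dataclass(frozen=True)
class PixelTable:
    """Long-format per-pixel counts: one row per pixel, one column per isotope.

    Rows are ordered row-major from the image top-left, so the table and the
    raster are exact inverses of one another.
    """

    width: int
    height: int
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.counts) != self.width * self.height:
            raise ValueError(
                f"{len(self.counts)} rows != width*height = "
                f"{self.width * self.height}"
            )
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("pixel table must be numeric")
        if np.nanmin(vals) < 0 if vals.size else False:
            raise ValueError("pixel table contains negative counts")

    @property
    def isotopes(self) -> list[str]:
        return list(self.counts.columns)

    def to_raster(self, isotope: str) -> np.ndarray:
        """Reshape one isotope column back to its (height, width) raster."""
        col = self.counts[isotope].to_numpy()
        return col.reshape(self.height, self.width)

    def to_image(self, isotope: str, pixel_size_um: float = 1.0) -> ChannelImage:
        return ChannelImage(self.to_raster(isotope), isotope, pixel_size_um)

    @classmethod
    def from_rasters(
        cls, rasters: Mapping[str, np.ndarray] | Iterable[ChannelImage]
    ) -> "PixelTable":
        """Build a table from same-shaped rasters, row-major from the top-left."""
        if not isinstance(rasters, Mapping):
            rasters = {img.isotope: img.pixels for img in rasters}
        items = list(rasters.items())
        if not items:
            raise ValueError("no rasters given")
        h, w = np.asarray(items[0][1]).shape
        data = {}
        for iso, arr in items:
            arr = np.asarray(arr)
            if arr.shape != (h, w):
                raise ValueError(f"raster {iso} shape {arr.shape} != {(h, w)}")
            data[iso] = arr.reshape(-1)
        return cls(width=w, height=h, counts=pd.DataFrame(data))
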