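"""Readers and writers for every raster and tabular format the pipeline touches.

Rasters: single-channel 16-bit TIFF per isotope (counts preserved bit-exactly),
multichannel stacks as ordered TIFF pages, PNG/TIFF integer label masks.
Tables: UTF-8 CSV with a header row and "." decimal — pixel tables (one row
per pixel), cell tables, droplet-standard tables, calibration curves.
Config: TOML panel mapping isotope → marker → role.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import ChannelImage, ImageStack, PixelTable, SegmentationMask

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_pixel_table",
    "write_pixel_table",
    "read_mask",
    "write_mask",
    "read_cell_table",
    "write_cell_table",
    "read_panel",
    "PanelEntry",
    "read_standards",
    "write_standards",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_quantified_map",
]


def read_image(
    path: str | Path, isotope: str, pixel_size_um: float = 1.0
) -> ChannelImage:
    """Read a single-channel TIFF into a :class:`ChannelImage`.

    The file must contain exactly one image page; a multi-page stack read
    through this single-channel entry point is a contract violation and
    raises with the page count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        pixels = tif.asarray()
    if pixels.ndim == 3 and pixels.shape[-1] == 1:
        pixels = pixels[..., 0]
    if n_pages != 1 or pixels.ndim != 2:
        n_samples = max(n_pages, pixels.shape[0] if pixels.ndim == 3 else 1)
        raise ValueError(
            f"{path} has {n_samples} pages; read_image handles single-channel "
            "TIFFs only — use read_stack for multichannel files"
        )
    return ChannelImage(pixels=pixels, isotope=isotope, pixel_size_um=pixel_size_um)


def write_image(img: ChannelImage, path: str | Path) -> Path:
    """Write a count raster as TIFF; 16-bit when the counts fit, else float32."""
    path = Path(path)
    px = img.pixels
    if np.issubdtype(px.dtype, np.integer) and px.max(initial=0) <= np.iinfo("uint16").max:
        out = px.astype(np.uint16)
    elif np.issubdtype(px.dtype, np.floating):
        out = px.astype(np.float32)
    else:
        out = px
    tifffile.imwrite(path, out)
    return path


def read_stack(
    path: str | Path, isotopes: Sequence[str], pixel_size_um: float = 1.0,
    panel: dict[str, str] | None = None,
) -> ImageStack:
    """Read a multichannel TIFF (ordered pages) into an :class:`ImageStack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(isotopes):
        raise ValueError(
            f"{path} holds {arr.shape[0]} pages but {len(isotopes)} isotope "
            "labels were given"
        )
    channels = [
        ChannelImage(arr[i], iso, pixel_size_um) for i, iso in enumerate(isotopes)
    ]
    return ImageStack(channels, panel=panel or {})


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    arr = stack.as_array()
    if np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 65535:
        arr = arr.astype(np.uint16)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr)
    return path


def read_pixel_table(path: str | Path, width: int, height: int) -> PixelTable:
    """Read a per-pixel CSV (one row per pixel, one column per isotope).

    Rows must be in row-major order from the image top-left and there must be
    exactly ``width × height`` of them.
    """
    df = pd.read_csv(path)
    if len(df) != width * height:
        raise ValueError(
            f"{path} has {len(df)} rows, expected width*height = {width * height}"
        )
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path} contains negative counts")
    return PixelTable(width=width, height=height, counts=df)


def write_pixel_table(table: PixelTable, path: str | Path) -> Path:
    path = Path(path)
    table.counts.to_csv(path, index=False)
    return path


def read_mask(path: str | Path) -> SegmentationMask:
    """Read an integer label mask from PNG or TIFF.

    Labels are relabeled to consecutive 1..N (background stays 0).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        # RGB(A) masks are ambiguous unless all bands agree
        if not (arr[..., 0] == arr.transpose(2, 0, 1)).all():
            raise ValueError(f"{path} is multi-band with disagreeing bands")
        arr = arr[..., 0]
    if not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr != np.round(arr)):
            raise ValueError(f"{path} contains non-integer mask values")
        arr = arr.astype(np.int64)
    return SegmentationMask(arr)


def write_mask(mask: SegmentationMask, path: str | Path) -> Path:
    path = Path(path)
    lab = mask.labels
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, lab.astype(np.int32))
    else:
        if lab.max() > 65535:
            raise ValueError("PNG masks support at most 65535 labels; use TIFF")
        Image.fromarray(lab.astype(np.uint16 if lab.max() > 255 else np.uint8)).save(
            path
        )
    return path


def write_cell_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cell table (or quantified cell table) as CSV, losslessly."""
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class PanelEntry:
    """One channel of the antibody/isotope panel."""

    isotope: str
    marker: str
    role: str  # nucleus | membrane | phenotype | metal

    ROLES = ("nucleus", "membrane", "phenotype", "metal")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValueError(f"unknown panel role {self.role!r}; one of {self.ROLES}")


def read_panel(path: str | Path) -> list[PanelEntry]:
    """Read a TOML panel config mapping isotope → marker name → role.

    Expected layout::

        [channels."193Ir"]
        marker = "DNA-intercalator"
        role = "nucleus"
    """
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    if "channels" not in cfg:
        raise ValueError(f"{path}: missing [channels] table")
    entries = []
    for isotope, spec in cfg["channels"].items():
        entries.append(
            PanelEntry(isotope=isotope, marker=spec["marker"], role=spec["role"])
        )
    return entries


# --- droplet standards and calibration curves -------------------------------

STANDARDS_COLUMNS = ["element", "concentration_ug_per_L", "volume_pL",
                     "integrated_counts", "blank_flag"]


def read_standards(path: str | Path) -> pd.DataFrame:
    """Read a droplet-standard table (element, concentration, volume, counts)."""
    df = pd.read_csv(path)
    missing = set(STANDARDS_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing standard columns {sorted(missing)}")
    return df


def write_standards(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


CALIBRATION_COLUMNS = ["element", "slope", "intercept", "r2",
                       "range_min_fg", "range_max_fg", "n_points"]


def write_calibration_csv(curves, path: str | Path) -> Path:
    """Write calibration curves with schema
    element, slope, intercept, r2, range_min_fg, range_max_fg, n_points."""
    path = Path(path)
    rows = [
        {
            "element": c.element,
            "slope": c.slope,
            "intercept": c.intercept,
            "r2": c.r_squared,
            "range_min_fg": c.linear_range_fg[0],
            "range_max_fg": c.linear_range_fg[1],
            "n_points": c.n_points,
        }
        for c in curves
    ]
    pd.DataFrame(rows, columns=CALIBRATION_COLUMNS).to_csv(path, index=False)
    return path


def read_calibration_csv(path: str | Path):
    """Read calibration curves written by :func:`write_calibration_csv`."""
    from .calibration import CalibrationCurve

    df = pd.read_csv(path)
    return [
        CalibrationCurve(
            element=row["element"],
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r_squared=float(row["r2"]),
            linear_range_fg=(float(row["range_min_fg"]), float(row["range_max_fg"])),
            n_points=int(row["n_points"]),
        )
        for _, row in df.iterrows()
    ]


def write_quantified_map(amounts: np.ndarray, path: str | Path) -> Path:
    """Export a quantified per-pixel map (fg/pixel) as 32-bit float TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(amounts, dtype=np.float32))
    return path
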