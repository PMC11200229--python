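"""End-to-end pipeline: validated TOML config in, artifact directory out.

Stages run in a fixed order — preprocess → segment → features → calibrate →
quantify → phenotype — each consuming and producing only documented files,
so any stage can be replaced by an external tool's output (e.g. an imported
segmentation mask). A manifest records versions, seeds and a parameter hash;
rerunning with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .calibration import CalibrationCurve, DropletStandard, fit_calibration, quantify_cells
from .phenotyping import (
    cluster_phenograph,
    embed_umap,
    cluster_heatmap,
    filter_outliers,
    project_clusters,
    scale_features,
    size_normalize,
)
from .preprocess import HotPixelParams, median_filter, remove_hot_pixels
from .segmentation import (
    extract_features,
    filter_border_objects,
    filter_by_size,
    watershed_segment,
)
from .types import ImageStack

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "StageError"]

STAGES = ("preprocess", "segment", "features", "calibrate", "quantify", "phenotype")

_ALLOWED_KEYS = {
    "paths": {"images", "output", "mask", "standards", "calibration"},
    "preprocess": {"hot_threshold", "hot_window", "median_radius"},
    "segment": {"expected_diameter_um", "min_size_px", "max_size_px"},
    "quantify": {"channels", "subtract_intercept"},
    "phenotype": {"channels", "k_neighbors", "resolution", "upper_pct", "scaling"},
    "seeds": {"seed"},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.fingerprint = fingerprint


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (single TOML file)."""

    images_dir: Path
    output_dir: Path
    panel: list  # list[mio.PanelEntry]
    mask_path: Path | None = None
    standards_path: Path | None = None
    calibration_path: Path | None = None
    hot_threshold: float = 50.0
    hot_window: int = 3
    median_radius: int = 1
    expected_diameter_um: float = 10.0
    min_size_px: int = 10
    max_size_px: int = 10_000
    quantify_channels: list[str] = field(default_factory=list)
    subtract_intercept: bool = True
    phenotype_channels: list[str] = field(default_factory=list)
    k_neighbors: int = 30
    resolution: float = 1.0
    upper_pct: float = 99.5
    scaling: str = "minmax"
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        unknown_sections = set(cfg) - (set(_ALLOWED_KEYS) | {"panel"})
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        for section, allowed in _ALLOWED_KEYS.items():
            extra = set(cfg.get(section, {})) - allowed
            if extra:
                raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
        if "panel" not in cfg or "channels" not in cfg.get("panel", {}):
            raise ValueError("config must define [panel.channels.<isotope>] entries")
        panel = [
            mio.PanelEntry(isotope=iso, marker=spec["marker"], role=spec["role"])
            for iso, spec in cfg["panel"]["channels"].items()
        ]
        paths = cfg.get("paths", {})
        if "images" not in paths or "output" not in paths:
            raise ValueError("[paths] must set 'images' and 'output'")
        base = path.parent
        resolve = lambda p: (base / p) if not Path(p).is_absolute() else Path(p)
        pre = cfg.get("preprocess", {})
        seg = cfg.get("segment", {})
        qua = cfg.get("quantify", {})
        phe = cfg.get("phenotype", {})
        return cls(
            images_dir=resolve(paths["images"]),
            output_dir=resolve(paths["output"]),
            panel=panel,
            mask_path=resolve(paths["mask"]) if "mask" in paths else None,
            standards_path=resolve(paths["standards"]) if "standards" in paths else None,
            calibration_path=(
                resolve(paths["calibration"]) if "calibration" in paths else None
            ),
            hot_threshold=float(pre.get("hot_threshold", 50.0)),
            hot_window=int(pre.get("hot_window", 3)),
            median_radius=int(pre.get("median_radius", 1)),
            expected_diameter_um=float(seg.get("expected_diameter_um", 10.0)),
            min_size_px=int(seg.get("min_size_px", 10)),
            max_size_px=int(seg.get("max_size_px", 10_000)),
            quantify_channels=list(qua.get("channels", [])),
            subtract_intercept=bool(qua.get("subtract_intercept", True)),
            phenotype_channels=list(phe.get("channels", [])),
            k_neighbors=int(phe.get("k_neighbors", 30)),
            resolution=float(phe.get("resolution", 1.0)),
            upper_pct=float(phe.get("upper_pct", 99.5)),
            scaling=str(phe.get("scaling", "minmax")),
            seed=int(cfg.get("seeds", {}).get("seed", 0)),
        )

    def validate_inputs(self) -> None:
        """Pre-flight checks; nothing is written if these fail."""
        if not self.images_dir.is_dir():
            raise FileNotFoundError(f"images directory {self.images_dir} not found")
        for entry in self.panel:
            if self._image_path(entry.isotope) is None:
                raise FileNotFoundError(
                    f"no TIFF for panel channel {entry.isotope} in {self.images_dir}"
                )
        if self.quantify_channels and not (self.standards_path or self.calibration_path):
            raise ValueError(
                "quantification requested but neither a standards table nor a "
                "calibration file is configured"
            )
        for p in (self.mask_path, self.standards_path, self.calibration_path):
            if p is not None and not p.exists():
                raise FileNotFoundError(p)

    def _image_path(self, isotope: str) -> Path | None:
        for suffix in (".tif", ".tiff"):
            p = self.images_dir / f"{isotope}{suffix}"
            if p.exists():
                return p
        return None

    def parameter_hash(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items()) if k != "panel"
        }
        payload["panel"] = [(e.isotope, e.marker, e.role) for e in self.panel]
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _role_isotopes(panel, role: str) -> list[str]:
    return [e.isotope for e in panel if e.role == role]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the artifact directory."""
    config.validate_inputs()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "stages": [],
        "outputs": [],
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(p.relative_to(out)) for p in paths)

    fingerprint = str(config.images_dir)
    try:
        stage = "preprocess"
        stack = ImageStack(
            [
                mio.read_image(config._image_path(e.isotope), e.isotope)
                for e in config.panel
            ],
            panel={e.isotope: e.marker for e in config.panel},
        )
        hot = HotPixelParams(
            neighborhood_size=config.hot_window, threshold=config.hot_threshold
        )
        cleaned = ImageStack(
            [remove_hot_pixels(c, hot) for c in stack.channels], panel=stack.panel
        )
        pre_dir = out / "preprocessed"
        pre_dir.mkdir(exist_ok=True)
        written = [
            mio.write_image(c, pre_dir / f"{c.isotope}.tif") for c in cleaned.channels
        ]
        record(stage, *written)

        stage = "segment"
        if config.mask_path is not None:
            mask = mio.read_mask(config.mask_path)
        else:
            nucleus = _role_isotopes(config.panel, "nucleus")
            membrane = _role_isotopes(config.panel, "membrane")
            if not nucleus or not membrane:
                raise ValueError("panel must define a nucleus and a membrane channel")
            # segmentation sees the median-filtered raw stack (the median also
            # suppresses spikes); hot-pixel-cleaned channels are reserved for
            # intensity measurement, where the filter must not erode nuclei
            seg_stack = ImageStack(
                [
                    median_filter(stack.channel(membrane[0]), config.median_radius),
                    median_filter(stack.channel(nucleus[0]), config.median_radius),
                ]
            )
            mask = watershed_segment(seg_stack, config.expected_diameter_um)
        mask = filter_border_objects(mask)
        mask = filter_by_size(mask, config.min_size_px, config.max_size_px)
        mask_path = mio.write_mask(mask, out / "mask.png")
        record(stage, mask_path)

        stage = "features"
        cells = extract_features(mask, cleaned)
        cells_path = mio.write_cell_table(cells, out / "cells.csv")
        record(stage, cells_path)

        stage = "calibrate"
        curves: list[CalibrationCurve] = []
        if config.calibration_path is not None:
            curves = mio.read_calibration_csv(config.calibration_path)
        elif config.standards_path is not None:
            standards = mio.read_standards(config.standards_path)
            for element, grp in standards.groupby("element"):
                curves.append(
                    fit_calibration(
                        [
                            DropletStandard(
                                element=str(element),
                                concentration_ug_per_L=row["concentration_ug_per_L"],
                                volume_pL=row["volume_pL"],
                                integrated_counts=row["integrated_counts"],
                                blank_flag=bool(row.get("blank_flag", False)),
                            )
                            for _, row in grp.iterrows()
                        ]
                    )
                )
        if curves:
            cal_path = mio.write_calibration_csv(curves, out / "calibration.csv")
            record(stage, cal_path)
        else:
            record(stage)

        stage = "quantify"
        quantified = cells
        if config.quantify_channels:
            by_element = {c.element: c for c in curves}
            for ch in config.quantify_channels:
                if ch not in by_element:
                    raise KeyError(f"no calibration curve for channel {ch!r}")
                quantified = quantify_cells(
                    quantified,
                    by_element[ch],
                    channels=[ch],
                    subtract_intercept=config.subtract_intercept,
                )
        qpath = mio.write_cell_table(quantified, out / "quantified_cells.csv")
        record(stage, qpath)

        stage = "phenotype"
        pheno_channels = config.phenotype_channels or _role_isotopes(
            config.panel, "phenotype"
        )
        written = []
        if pheno_channels and len(cells) > config.k_neighbors:
            fm = size_normalize(cells, channels=pheno_channels)
            fm = filter_outliers(fm, config.upper_pct)
            fm = scale_features(fm, config.scaling)
            clusters = cluster_phenograph(
                fm,
                k_neighbors=config.k_neighbors,
                resolution=config.resolution,
                seed=config.seed,
            )
            labels = pd.DataFrame(
                {"cell_id": clusters.cell_ids, "cluster": clusters.labels}
            )
            written.append(mio.write_cell_table(labels, out / "clusters.csv"))
            coords = embed_umap(fm, seed=config.seed)
            umap_df = pd.DataFrame(
                {"cell_id": fm.cell_ids, "umap_x": coords[:, 0], "umap_y": coords[:, 1]}
            )
            written.append(mio.write_cell_table(umap_df, out / "umap.csv"))
            heat = cluster_heatmap(fm, clusters)
            heat_path = out / "cluster_heatmap.csv"
            heat.to_csv(heat_path)
            written.append(heat_path)
            overlay = project_clusters(mask, clusters)
            overlay_path = out / "cluster_overlay.tif"
            mio.write_quantified_map(overlay.astype(np.float32), overlay_path)
            written.append(overlay_path)
        else:
            logger.info("phenotyping skipped: no channels or too few cells")
        record(stage, *written)
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, fingerprint, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
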