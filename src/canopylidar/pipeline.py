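"""End-to-end orchestration: LAS in, per-plot trait table out.

Stages run in the fixed order denoise -> ground classification -> height
normalization -> CHM rasterization -> plot segmentation -> per-plot trait and
spectral-index analysis -> export (trait CSV, processed LAS, inspection
images, JSON-lines log).  Re-running with the same configuration and seed
reproduces the trait CSV byte-identically.

The pipeline expects the trial to be axis-aligned in the geo frame (the
synthetic generator and clipped ROIs are); :func:`canopylidar.chm.align_perspective`
is available for imagery that needs a four-marker warp first.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import canopyindex, chm, cloudio, plotseg, preprocess, traits
from .synthfield import FieldLayout

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and partial-output manifest."""

    def __init__(self, stage: str, message: str, manifest: dict):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    input_path: str
    output_dir: str
    roi_markers: str | None = None
    resolution_cm: float = 1.0
    h_black: float = 0.0
    h_white: float = 160.0
    denoise: preprocess.DenoiseParams = field(default_factory=preprocess.DenoiseParams)
    ground: preprocess.GroundFilterParams = field(default_factory=preprocess.GroundFilterParams)
    segmentation: plotseg.SegmentationParams = field(default_factory=plotseg.SegmentationParams)
    voxel: traits.VoxelParams = field(default_factory=traits.VoxelParams)
    dci_a: int = -100
    dci_b: int = 100
    max_edge: float = 0.2
    layout: FieldLayout | None = None
    write_las: bool = True
    write_images: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_path).exists():
            raise FileNotFoundError(f"input cloud not found: {self.input_path}")
        if self.roi_markers is not None and not Path(self.roi_markers).exists():
            raise FileNotFoundError(f"ROI marker file not found: {self.roi_markers}")
        if self.resolution_cm <= 0:
            raise ValueError("resolution must be positive")
        if self.h_white <= self.h_black:
            raise ValueError("grayscale calibration requires h_white > h_black")


def _plot_points(cloud, origin, resolution_cm, rect_px):
    x0, y0, x1, y1 = rect_px
    res_m = resolution_cm / 100.0
    gx0 = origin[0] + x0 * res_m
    gx1 = origin[0] + x1 * res_m
    gy1 = origin[1] - y0 * res_m  # raster row 0 is the northern edge
    gy0 = origin[1] - y1 * res_m
    sel = (
        (cloud.x >= gx0) & (cloud.x <= gx1)
        & (cloud.y >= gy0) & (cloud.y <= gy1)
        & (cloud.classification == cloudio.ABOVE_GROUND)
    )
    return cloud.subset(sel), (gx0, gy0, gx1, gy1)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the output manifest (paths plus the
    in-memory trait table under ``"traits"``)."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}}
    log_path = out_dir / "run_log.jsonl"
    log_fh = open(log_path, "w")
    manifest["outputs"]["log"] = str(log_path)

    def log(stage: str, **info):
        rec = {"stage": stage, **info}
        log_fh.write(json.dumps(rec, default=str) + "\n")
        log_fh.flush()

    def fail(stage: str, exc: Exception):
        log(stage, error=str(exc))
        log_fh.close()
        raise PipelineError(stage, str(exc), manifest) from exc

    t0 = time.time()
    log("config", **{k: v for k, v in asdict(config).items()})

    try:
        cloud = cloudio.read_cloud(config.input_path)
        if config.roi_markers:
            markers = cloudio.RoiMarkers.from_csv(config.roi_markers)
            cloud = cloudio.clip_roi(cloud, markers)
        log("load", n_points=len(cloud))
    except Exception as exc:  # noqa: BLE001 - stage boundary
        fail("load", exc)

    try:
        clean, outliers = preprocess.denoise(cloud, config.denoise)
        log("denoise", n_clean=len(clean), n_outliers=len(outliers))
    except Exception as exc:
        fail("denoise", exc)

    try:
        labeled = preprocess.classify_ground(clean, config.ground)
        normalized = preprocess.normalize_heights(labeled, config.ground.radius)
        n_ground = int((normalized.classification == cloudio.GROUND).sum())
        log("normalize", n_ground=n_ground, n_above=len(normalized) - n_ground)
    except Exception as exc:
        fail("normalize", exc)

    try:
        raster = chm.rasterize_chm(
            normalized, config.resolution_cm, max_edge=config.max_edge
        )
        enc = chm.GrayEncoding(config.h_black, config.h_white)
        image = chm.encode_grayscale(raster, enc)
        log("chm", shape=list(raster.shape), origin=list(raster.origin))
    except Exception as exc:
        fail("chm", exc)

    try:
        grid = plotseg.segment_plots(image, config.segmentation, config.layout)
        log("segment", n_plots=len(grid))
    except Exception as exc:
        fail("segment", exc)

    try:
        records = []
        curves = []
        for plot in grid.plots:
            pts, rect_geo = _plot_points(
                normalized, raster.origin, config.resolution_cm, plot.rect
            )
            rec: dict = {
                "plot_row": plot.row_id,
                "plot_col": plot.col_id,
                "x0_px": plot.rect[0], "y0_px": plot.rect[1],
                "x1_px": plot.rect[2], "y1_px": plot.rect[3],
                "point_count": len(pts),
                "flags": ";".join(plot.flags),
            }
            if len(pts) == 0:
                rec.update({
                    "height_h10": np.nan, "coverage": 0.0,
                    "surface_area_raw": np.nan, "vi_3d": np.nan, "pi_3d": np.nan,
                    "flags": ";".join(plot.flags + ["empty_plot"]),
                })
                records.append(rec)
                curves.append(None)
                continue
            rec["height_h10"] = traits.plot_height(pts.z)
            coverage, cov_flags = traits.canopy_coverage(pts.x, pts.y, pts.z, rect_geo)
            rec["coverage"] = coverage
            area, area_flags = traits.surface_area_3d(pts.x, pts.y, pts.z, config.voxel)
            rec["surface_area_raw"] = area
            vi, pi = traits.voxel_indices(pts.x, pts.y, pts.z, rect_geo, config.voxel)
            rec["vi_3d"], rec["pi_3d"] = vi, pi
            x0, y0, x1, y1 = plot.rect
            curve = canopyindex.canopy_curve_for_image(
                image[y0:y1, x0:x1], config.dci_a, config.dci_b
            )
            curves.append(curve)
            rec["gauss_amplitude"] = curve.amplitude
            rec["gauss_centre"] = curve.centre
            rec["gauss_sigma"] = curve.sigma
            rec["fit_ok"] = curve.fit_ok
            rec["curve_auc"] = canopyindex.curve_auc(curve)
            rec["curvature"] = (
                canopyindex.curve_curvature(curve) if curve.fit_ok else np.nan
            )
            all_flags = plot.flags + cov_flags + area_flags
            rec["flags"] = ";".join(all_flags)
            records.append(rec)

        table = traits.trait_table(records)
        aucs = table["curve_auc"].to_numpy(dtype=np.float64) if "curve_auc" in table else None
        if aucs is not None:
            ok = np.isfinite(aucs) & (aucs > 0)
            dci = np.full(len(table), np.nan)
            if ok.sum() >= 2 and aucs[ok].min() < aucs[ok].max():
                dci[ok] = canopyindex.compute_3dci(aucs[ok])
            table["dci_3d"] = dci
        log("traits", n_rows=len(table))
    except Exception as exc:
        fail("traits", exc)

    try:
        csv_path = out_dir / "traits.csv"
        table.to_csv(csv_path, index=False, float_format="%.6g")
        manifest["outputs"]["traits_csv"] = str(csv_path)
        grid_csv = out_dir / "plots.csv"
        grid.to_frame().to_csv(grid_csv, index=False)
        manifest["outputs"]["plots_csv"] = str(grid_csv)
        if config.write_las:
            las_path = out_dir / "processed.las"
            cloudio.write_cloud(normalized, las_path)
            manifest["outputs"]["processed_las"] = str(las_path)
        if config.write_images:
            from skimage.io import imsave

            img_path = out_dir / "chm.png"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imsave(img_path, image)
            manifest["outputs"]["chm_png"] = str(img_path)
        log("export", seconds=round(time.time() - t0, 2),
            **{k: v for k, v in manifest["outputs"].items()})
    except Exception as exc:
        fail("export", exc)

    log_fh.close()
    manifest["traits"] = table
    manifest["grid"] = grid
    manifest["n_plots"] = len(grid)
    return manifest
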