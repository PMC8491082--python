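"""Synthetic field point clouds with known per-plot ground truth.

The generator emulates a drilled cereal trial: rectangular plots on a gently
sloped, noisy terrain, with within-plot drill-row structure and a spike-scale
height texture whose variance is a single dial.  Every downstream stage of the
pipeline (denoising, ground filtering, CHM rasterization, plot segmentation,
trait extraction, spectral canopy index) can therefore be tested against exact
truth without any field data.

Canopy points are a mixture of two components per plot: points scattered
around drill-row centrelines (giving the CHM the vertical stripe periodicity
that the spectral stage detects) and a uniform "canopy closure" component over
the whole plot rectangle (the closed canopy of a heading-stage crop, which
also makes the plot boundary, not the row band, the detectable edge).  Closure
points sit a few centimetres below row points, so rows remain visible as
height relief on the interpolated canopy surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cloudio import ABOVE_GROUND, GROUND, PointCloud

__all__ = [
    "FieldLayout",
    "CanopySpec",
    "TerrainSpec",
    "generate_field",
    "inject_outliers",
    "TRIAL_LAYOUT",
]


@dataclass(frozen=True)
class FieldLayout:
    """Rectangular grid of plots.

    Defaults mirror a winter-wheat N-response trial: 2 x 3 m plots with six
    drill rows at 0.15 m spacing and 0.30 m gaps between plots.  ``plot_width``
    runs along x (the drill rows are parallel to y), ``plot_length`` along y.
    """

    n_plot_rows: int = 1
    n_plot_cols: int = 1
    plot_width: float = 2.0
    plot_length: float = 3.0
    inter_plot_gap: float = 0.30
    drill_rows_per_plot: int = 6
    drill_row_spacing: float = 0.15
    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.n_plot_rows < 1 or self.n_plot_cols < 1:
            raise ValueError("plot grid counts must be >= 1")
        if self.drill_rows_per_plot < 1:
            raise ValueError("drill_rows_per_plot must be >= 1")
        for name in ("plot_width", "plot_length", "inter_plot_gap",
                     "drill_row_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def n_plots(self) -> int:
        return self.n_plot_rows * self.n_plot_cols

    @property
    def field_width(self) -> float:
        return (2 * self.margin + self.n_plot_cols * self.plot_width
                + (self.n_plot_cols - 1) * self.inter_plot_gap)

    @property
    def field_length(self) -> float:
        return (2 * self.margin + self.n_plot_rows * self.plot_length
                + (self.n_plot_rows - 1) * self.inter_plot_gap)

    def plot_rectangle(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of a plot in field metres; plot row 0 is the
        northern (largest-y) row, matching raster row 0."""
        x0 = self.margin + col * (self.plot_width + self.inter_plot_gap)
        y1 = self.field_length - self.margin - row * (self.plot_length + self.inter_plot_gap)
        return (x0, y1 - self.plot_length, x0 + self.plot_width, y1)


#: Layout of one N-treatment block of the trial: three replicates of 54
#: varieties (162 plots) arranged 9 rows x 18 columns.
TRIAL_LAYOUT = FieldLayout(n_plot_rows=9, n_plot_cols=18)


@dataclass(frozen=True)
class CanopySpec:
    """Per-plot canopy description.

    mean_height/height_sd are in cm; ``height_sd`` is the spike-scale texture
    variance dial.  ``point_density`` is canopy points per m^2 of plot.
    ``row_point_fraction`` is the share of points tied to drill rows (the rest
    is uniform closure); ``row_relief_cm`` is how far the inter-row canopy sits
    below the row tops.
    """

    mean_height: float = 80.0
    height_sd: float = 3.0
    coverage_fraction: float = 1.0
    point_density: float = 1500.0
    row_point_fraction: float = 0.5
    row_relief_cm: float = 8.0
    row_scatter: float = 0.04  # lateral scatter sd around a row centreline (m)

    def __post_init__(self) -> None:
        if self.mean_height < 0:
            raise ValueError("mean_height must be >= 0")
        if self.height_sd < 0:
            raise ValueError("height_sd must be >= 0")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in [0, 1]")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")
        if not 0.0 <= self.row_point_fraction <= 1.0:
            raise ValueError("row_point_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TerrainSpec:
    """Ground surface: base elevation plus linear slopes and Gaussian
    roughness (cm).  ``ground_point_density`` is ground returns per m^2 over
    the whole field (LiDAR penetrates the canopy, so ground points exist under
    plots too)."""

    slope_x: float = 0.0
    slope_y: float = 0.0
    ground_roughness_sd: float = 0.0  # cm
    base_elevation: float = 0.0
    ground_point_density: float = 800.0

    def __post_init__(self) -> None:
        if self.ground_roughness_sd < 0:
            raise ValueError("ground_roughness_sd must be >= 0")
        if self.ground_point_density <= 0:
            raise ValueError("ground_point_density must be positive")

    def surface_z(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Smooth terrain elevation (without roughness) at (x, y)."""
        return self.base_elevation + self.slope_x * np.asarray(x) + self.slope_y * np.asarray(y)


def _row_offsets(layout: FieldLayout) -> np.ndarray:
    """Drill-row centreline offsets from the plot centre, along x (m)."""
    n = layout.drill_rows_per_plot
    return (np.arange(n) - (n - 1) / 2.0) * layout.drill_row_spacing


def _occupancy_coverage(px: np.ndarray, py: np.ndarray,
                        rect: tuple[float, float, float, float]) -> float:
    """Coverage ground truth: the same 5 cm occupancy-grid definition the
    coverage trait measures, applied to all generated canopy points."""
    from .traits import occupancy_coverage

    return occupancy_coverage(px, py, rect)


def generate_field(
    layout: FieldLayout,
    canopy: CanopySpec | list[CanopySpec],
    terrain: TerrainSpec = TerrainSpec(),
    seed: int = 0,
) -> tuple[PointCloud, pd.DataFrame]:
    """Generate a labelled field point cloud and its ground-truth trait table.

    Parameters
    ----------
    layout
        Plot grid geometry.
    canopy
        One :class:`CanopySpec` per plot (row-major, length
        ``n_plot_rows * n_plot_cols``), or a single spec applied to every plot.
    terrain
        Ground surface model.
    seed
        Seeds every random draw; the same seed gives byte-identical output.

    Returns
    -------
    cloud
        Ground points (class 2) on the terrain surface and canopy points
        (class 5) at terrain + plant height.
    truth
        One row per plot: ``plot_row, plot_col, true_mean_height_cm,
        true_h10_cm, true_coverage, x0, y0, x1, y1`` (rectangle in field
        metres).  Height truths are recomputed from the generated points
        (sort-and-average); coverage by grid occupancy.
    """
    if isinstance(canopy, CanopySpec):
        canopy = [canopy] * layout.n_plots
    if len(canopy) != layout.n_plots:
        raise ValueError(
            f"canopy list length {len(canopy)} != "
            f"{layout.n_plot_rows} x {layout.n_plot_cols} plots"
        )
    rng = np.random.default_rng(seed)

    xs, ys, zs, labels = [], [], [], []

    # ground returns over the whole field
    area = layout.field_width * layout.field_length
    n_ground = int(round(terrain.ground_point_density * area))
    gx = rng.uniform(0.0, layout.field_width, n_ground)
    gy = rng.uniform(0.0, layout.field_length, n_ground)
    gz = terrain.surface_z(gx, gy)
    if terrain.ground_roughness_sd > 0:
        gz = gz + rng.normal(0.0, terrain.ground_roughness_sd / 100.0, n_ground)
    xs.append(gx)
    ys.append(gy)
    zs.append(gz)
    labels.append(np.full(n_ground, GROUND, dtype=np.uint8))

    truth_rows = []
    offsets = _row_offsets(layout)
    for r in range(layout.n_plot_rows):
        for c in range(layout.n_plot_cols):
            spec = canopy[r * layout.n_plot_cols + c]
            rect = layout.plot_rectangle(r, c)
            x0, y0, x1, y1 = rect
            n_pts = int(round(spec.point_density * layout.plot_width * layout.plot_length))
            if n_pts == 0 or spec.mean_height == 0:
                truth_rows.append((r, c, 0.0, 0.0, 0.0, *rect))
                continue
            # canopy occupies a sub-rectangle of the footprint along y
            cov_y1 = y0 + spec.coverage_fraction * (y1 - y0)
            on_row = rng.random(n_pts) < spec.row_point_fraction
            px = np.empty(n_pts)
            n_row = int(on_row.sum())
            centre_x = (x0 + x1) / 2.0
            row_idx = rng.integers(0, offsets.size, n_row)
            px[on_row] = centre_x + offsets[row_idx]
            if spec.row_scatter > 0:
                px[on_row] += rng.normal(0.0, spec.row_scatter, n_row)
            px[~on_row] = rng.uniform(x0, x1, n_pts - n_row)
            np.clip(px, x0, x1, out=px)
            py = rng.uniform(y0, cov_y1 if cov_y1 > y0 else y0, n_pts)
            heights = np.full(n_pts, spec.mean_height, dtype=np.float64)
            heights[~on_row] -= spec.row_relief_cm
            if spec.height_sd > 0:
                heights = heights + rng.normal(0.0, spec.height_sd, n_pts)
            np.clip(heights, 0.0, None, out=heights)
            pz = terrain.surface_z(px, py) + heights / 100.0
            xs.append(px)
            ys.append(py)
            zs.append(pz)
            labels.append(np.full(n_pts, ABOVE_GROUND, dtype=np.uint8))

            # ground truth recomputed from the generated points
            h_sorted = np.sort(heights)[::-1]
            n_top = int(np.ceil(0.10 * n_pts))
            truth_rows.append((
                r, c,
                float(heights.mean()),
                float(h_sorted[:n_top].mean()),
                _occupancy_coverage(px, py, rect),
                *rect,
            ))

    cloud = PointCloud(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
        np.concatenate(labels),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["plot_row", "plot_col", "true_mean_height_cm", "true_h10_cm",
                 "true_coverage", "x0", "y0", "x1", "y1"],
    )
    return cloud, truth


def inject_outliers(
    cloud: PointCloud,
    n: int,
    min_offset: float = 2.0,
    seed: int = 0,
) -> PointCloud:
    """Append ``n`` high-altitude stray points, each farther than
    ``min_offset`` metres from every original point; originals unchanged."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if min_offset <= 0:
        raise ValueError("min_offset must be positive")
    if n == 0:
        return cloud
    rng = np.random.default_rng(seed)
    z_top = cloud.z.max() if len(cloud) else 0.0
    ox = rng.uniform(cloud.x.min() if len(cloud) else 0.0,
                     cloud.x.max() if len(cloud) else 1.0, n)
    oy = rng.uniform(cloud.y.min() if len(cloud) else 0.0,
                     cloud.y.max() if len(cloud) else 1.0, n)
    # strictly above the cloud: vertical clearance alone guarantees the offset
    oz = z_top + min_offset * (1.0 + rng.random(n))
    from .cloudio import OUTLIER

    return PointCloud(
        np.concatenate([cloud.x, ox]),
        np.concatenate([cloud.y, oy]),
        np.concatenate([cloud.z, oz]),
        np.concatenate([cloud.classification, np.full(n, OUTLIER, np.uint8)]),
        cloud.z_unit,
    )
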