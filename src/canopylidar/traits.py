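"""Per-plot canopy traits: H10 height, canopy coverage, alpha-shape 3D
surface area, and voxel-occupancy biomass indices.

All operations take the normalized above-ground points of a single plot
(z in cm above the flattened ground).  Height is the mean of the highest 10%
of points (H10); coverage projects the highest 50% (H50) overhead onto an
occupancy grid; surface area voxelizes the points, down-samples, meshes the
voxel corner set with an alpha shape and sums the triangle areas; the voxel
index (3DVI) is the occupied fraction of the plot bounding volume and the
profile index (3DPI) sums per-height-bin occupied-cell fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from skimage.morphology import closing, remove_small_holes

__all__ = [
    "VoxelParams",
    "plot_height",
    "occupancy_coverage",
    "canopy_coverage",
    "alpha_shape_area",
    "surface_area_3d",
    "voxel_indices",
    "trait_table",
]


@dataclass(frozen=True)
class VoxelParams:
    """Voxelization scales in cm.  ``alpha`` is the alpha-shape radius;
    the default, twice the voxel size, closes single-voxel gaps while
    following the canopy surface."""

    voxel_size: float = 5.0
    downsample_size: float = 5.0
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.downsample_size <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")

    @property
    def alpha_cm(self) -> float:
        return self.alpha if self.alpha is not None else 2.0 * self.voxel_size


def _top_fraction(z: np.ndarray, fraction: float) -> np.ndarray:
    """The highest ceil(fraction * n) values of z (descending sort; ties at
    the cutoff resolved deterministically by sort order)."""
    n = z.size
    m = int(math.ceil(fraction * n))
    return np.sort(z)[::-1][:m]


def plot_height(z_cm: np.ndarray, fraction: float = 0.10) -> float:
    """Plot height (cm): average of the highest ``fraction`` of point
    heights (the H10 rule at the default)."""
    z = np.asarray(z_cm, dtype=np.float64)
    if z.size == 0:
        raise ValueError("empty plot")
    return float(_top_fraction(z, fraction).mean())


def occupancy_coverage(
    x: np.ndarray,
    y: np.ndarray,
    rect: tuple[float, float, float, float],
    cell_m: float = 0.05,
) -> float:
    """Occupied fraction of a ``cell_m`` grid spanning ``rect``
    (x0, y0, x1, y1 metres), after closing isolated empty cells inside the
    canopy (morphological closing + small-hole removal, the adaptive step of
    the overhead projection)."""
    x0, y0, x1, y1 = rect
    nx = max(1, int(round((x1 - x0) / cell_m)))
    ny = max(1, int(round((y1 - y0) / cell_m)))
    if np.size(x) == 0:
        return 0.0
    ix = np.clip(((np.asarray(x) - x0) / (x1 - x0) * nx).astype(int), 0, nx - 1)
    iy = np.clip(((np.asarray(y) - y0) / (y1 - y0) * ny).astype(int), 0, ny - 1)
    occupied = np.zeros((ny, nx), dtype=bool)
    occupied[iy, ix] = True
    closed = closing(occupied)
    closed = remove_small_holes(closed, max_size=8)
    return float(closed.mean())


def canopy_coverage(
    x: np.ndarray,
    y: np.ndarray,
    z_cm: np.ndarray,
    rect: tuple[float, float, float, float],
    fraction: float = 0.50,
    cell_m: float = 0.05,
) -> tuple[float, list[str]]:
    """Canopy coverage in [0, 1] over the plot footprint.

    The highest ``fraction`` of points (H50 by default) is projected
    overhead onto an occupancy grid spanning ``rect``; coverage is the
    occupied fraction of the footprint.  Empty plots return 0 with a flag.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z_cm, dtype=np.float64)
    if x.size == 0:
        return 0.0, ["empty_plot"]
    order = np.argsort(z)[::-1]
    m = int(math.ceil(fraction * z.size))
    keep = order[:m]
    return occupancy_coverage(x[keep], y[keep], rect, cell_m), []


def _occupied_voxels(
    x: np.ndarray, y: np.ndarray, z_cm: np.ndarray, size_cm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Unique occupied voxel indices and the grid origin (metres, cm for z)."""
    origin = np.array([x.min(), y.min(), z_cm.min()])
    size = np.array([size_cm / 100.0, size_cm / 100.0, size_cm])
    idx = np.floor((np.column_stack([x, y, z_cm]) - origin) / size).astype(np.int64)
    return np.unique(idx, axis=0), origin


def alpha_shape_area(points_m: np.ndarray, alpha_m: float) -> float:
    """Surface area (m^2) of the alpha-shape mesh of a 3D point set.

    Delaunay tetrahedralization filtered to tetrahedra whose circumradius is
    at most ``alpha_m``; the mesh is the set of triangular faces belonging to
    exactly one retained tetrahedron.  Raises ValueError on degenerate input.
    """
    pts = np.asarray(points_m, dtype=np.float64)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 points for an alpha shape")
    try:
        tet = Delaunay(pts)
    except QhullError:
        try:
            tet = Delaunay(pts, qhull_options="QJ")
        except QhullError as exc:
            raise ValueError("degenerate point set for alpha shape") from exc
    simplices = tet.simplices
    a, b, c, d = (pts[simplices[:, i]] for i in range(4))
    radii = _circumradius(a, b, c, d)
    keep = simplices[radii <= alpha_m]
    if keep.size == 0:
        raise ValueError("alpha too small: no tetrahedra retained")
    # boundary faces: appear in exactly one retained tetrahedron
    faces = np.sort(
        keep[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3), axis=1
    )
    uniq, counts = np.unique(faces, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    v0, v1, v2 = pts[boundary[:, 0]], pts[boundary[:, 1]], pts[boundary[:, 2]]
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    return float(areas.sum())


def _circumradius(a, b, c, d) -> np.ndarray:
    """Effective alpha radius of tetrahedra given their four vertex arrays.

    Non-degenerate tetrahedra use the circumsphere radius.  Zero-volume
    slivers (which gridded point sets produce in abundance) have an unbounded
    circumsphere although they occupy no space; they use the half-longest-edge
    lower bound of the minimum enclosing ball instead, so slivers interior to
    the shape stay in the complex and do not punch spurious boundary faces.
    """
    ba, ca, da = b - a, c - a, d - a
    sq = lambda v: (v * v).sum(axis=1)
    edge_sq = np.stack([sq(ba), sq(ca), sq(da), sq(c - b), sq(d - b), sq(d - c)])
    rhs = 0.5 * np.stack([sq(ba), sq(ca), sq(da)], axis=1)
    M = np.stack([ba, ca, da], axis=1)
    det = np.linalg.det(M)
    scale = edge_sq.max(axis=0) ** 1.5
    good = np.abs(det) > 1e-9 * np.maximum(scale, 1e-300)
    radii = np.sqrt(edge_sq.max(axis=0)) / 2.0
    if good.any():
        centre = np.linalg.solve(M[good], rhs[good][..., None])[..., 0]
        radii[good] = np.linalg.norm(centre, axis=1)
    return radii


def surface_area_3d(
    x: np.ndarray,
    y: np.ndarray,
    z_cm: np.ndarray,
    params: VoxelParams = VoxelParams(),
) -> tuple[float, list[str]]:
    """Raw 3D canopy surface area (m^2) of a plot.

    Points are packaged into ``voxel_size`` voxels, down-sampled to
    ``downsample_size`` occupancy (closing within-plot gaps), and the corner
    points of the occupied voxels are meshed with an alpha shape.  Voxel
    corners (not centres) give a flat canopy its physical one-voxel
    thickness, so the mesh of a thin slab closes to top + bottom + rim.
    Returns (area, flags); too few voxels yields NaN with a flag.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z_cm, dtype=np.float64)
    if x.size == 0:
        return float("nan"), ["empty_plot"]
    size = max(params.voxel_size, params.downsample_size)
    vox, origin = _occupied_voxels(x, y, z, size)
    if vox.shape[0] < 2:
        return float("nan"), ["too_few_voxels"]
    # corner points of each occupied voxel, de-duplicated
    shifts = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    corners = (vox[:, None, :] + shifts[None, :, :]).reshape(-1, 3)
    corners = np.unique(corners, axis=0)
    step = np.array([size / 100.0, size / 100.0, size / 100.0])
    pts = origin * np.array([1.0, 1.0, 0.01])  # z origin cm -> m
    pts = pts + corners * step
    try:
        area = alpha_shape_area(pts, params.alpha_cm / 100.0)
    except ValueError:
        return float("nan"), ["degenerate_mesh"]
    return area, []


def voxel_indices(
    x: np.ndarray,
    y: np.ndarray,
    z_cm: np.ndarray,
    rect: tuple[float, float, float, float],
    params: VoxelParams = VoxelParams(),
) -> tuple[float, float]:
    """(3DVI, 3DPI) voxel-occupancy indices of a plot.

    3DVI = occupied voxels / total voxels in the plot bounding volume
    (footprint x [0, max height]).  3DPI = sum over ``voxel_size`` height bins
    of the occupied-cell fraction of the footprint in that bin.  Both depend
    on occupancy only, so they are invariant to uniform density changes.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    z = np.asarray(z_cm, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty plot")
    s = params.voxel_size
    x0, y0, x1, y1 = rect
    nx = max(1, int(math.ceil((x1 - x0) / (s / 100.0))))
    ny = max(1, int(math.ceil((y1 - y0) / (s / 100.0))))
    nz = max(1, int(math.ceil(z.max() / s))) if z.max() > 0 else 1
    ix = np.clip(np.floor((x - x0) / (s / 100.0)).astype(int), 0, nx - 1)
    iy = np.clip(np.floor((y - y0) / (s / 100.0)).astype(int), 0, ny - 1)
    iz = np.clip(np.floor(z / s).astype(int), 0, nz - 1)
    occ = np.zeros((nz, ny, nx), dtype=bool)
    occ[iz, iy, ix] = True
    vi = float(occ.sum()) / (nx * ny * nz)
    pi = float(occ.reshape(nz, -1).mean(axis=1).sum())
    return vi, pi


def trait_table(per_plot: list[dict]) -> pd.DataFrame:
    """Assemble per-plot trait records into the exportable table, ordered by
    plot row then column, with the normalized surface index computed against
    the per-run maximum."""
    df = pd.DataFrame(per_plot)
    df = df.sort_values(["plot_row", "plot_col"]).reset_index(drop=True)
    if "surface_area_raw" in df:
        max_area = df["surface_area_raw"].max(skipna=True)
        if pd.notna(max_area) and max_area > 0:
            df["surface_index"] = df["surface_area_raw"] / max_area
        else:
            df["surface_index"] = np.nan
    return df
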