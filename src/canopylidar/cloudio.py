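"""Point cloud container, LAS I/O, ROI clipping, and geo/pixel coordinate maps.

Coordinates are metric metres with z up.  Classification follows the LAS
convention: 1 unclassified, 2 ground, 5 above-ground vegetation, 7 outlier.
After height normalization (see :mod:`canopylidar.preprocess`) ground points
carry z = 0 and above-ground points carry height in centimetres; the
``z_unit`` attribute records which convention a cloud is in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely

from ._las import LasFormatError, read_las, write_las

__all__ = [
    "UNCLASSIFIED",
    "GROUND",
    "ABOVE_GROUND",
    "OUTLIER",
    "PointCloud",
    "RoiMarkers",
    "read_cloud",
    "write_cloud",
    "clip_roi",
    "geo_to_pixel",
    "pixel_to_geo",
    "LasFormatError",
]

UNCLASSIFIED = 1
GROUND = 2
ABOVE_GROUND = 5
OUTLIER = 7


@dataclass
class PointCloud:
    """A set of 3D points with optional per-point class labels.

    Parameters
    ----------
    x, y, z
        Equal-length coordinate arrays in metres (z in cm once normalized).
    classification
        LAS class codes; defaults to unclassified.
    z_unit
        ``"m"`` for raw clouds, ``"cm"`` after height normalization.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray = field(default=None)  # type: ignore[assignment]
    z_unit: str = "m"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ValueError("x, y, z must have equal length")
        if self.classification is None:
            self.classification = np.full(self.x.shape, UNCLASSIFIED, dtype=np.uint8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.uint8)
            if self.classification.shape != self.x.shape:
                raise ValueError("classification length must match coordinates")
        for arr in (self.x, self.y, self.z):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.x.size

    def subset(self, mask: np.ndarray) -> "PointCloud":
        """Return the points selected by a boolean mask or index array."""
        return PointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            self.classification[mask], self.z_unit,
        )

    def with_classification(self, classification: np.ndarray) -> "PointCloud":
        return replace(self, classification=np.asarray(classification, np.uint8))

    @property
    def xyz(self) -> np.ndarray:
        """N x 3 coordinate matrix."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class RoiMarkers:
    """Four ROI corner geo-coordinates in the fixed order
    upper-left, upper-right, lower-left, lower-right."""

    upper_left: tuple[float, float]
    upper_right: tuple[float, float]
    lower_left: tuple[float, float]
    lower_right: tuple[float, float]

    def polygon(self) -> shapely.Polygon:
        # ring order: UL -> UR -> LR -> LL
        poly = shapely.Polygon(
            [self.upper_left, self.upper_right, self.lower_right, self.lower_left]
        )
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(
                "ROI markers form a degenerate or self-intersecting quadrilateral"
            )
        return poly

    @property
    def corners(self) -> np.ndarray:
        """4 x 2 array in UL, UR, LL, LR order."""
        return np.asarray(
            [self.upper_left, self.upper_right, self.lower_left, self.lower_right],
            dtype=np.float64,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RoiMarkers":
        """Load markers from a 4-row CSV of x,y geo-coordinates (UL,UR,LL,LR)."""
        rows = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        if rows.shape != (4, 2):
            raise ValueError(f"marker file must contain 4 rows of x,y; got {rows.shape}")
        return cls(*(tuple(r) for r in rows))


def read_cloud(path: str | Path) -> PointCloud:
    """Read a LAS file (point formats 0-3; geometry and classification only)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    x, y, z, classification = read_las(path)
    if x.size == 0:
        warnings.warn(f"{path}: LAS file contains no points", stacklevel=2)
    return PointCloud(x, y, z, classification)


def write_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write a cloud as LAS 1.2 (point format 0, 1 mm scale quantum)."""
    write_las(path, cloud.x, cloud.y, cloud.z, cloud.classification)


def clip_roi(cloud: PointCloud, markers: RoiMarkers) -> PointCloud:
    """Return exactly the points inside the marker quadrilateral.

    Boundary points count as inside, so a cloud is partitioned exactly between
    the clip and its complement.
    """
    poly = markers.polygon()
    pts = shapely.points(cloud.x, cloud.y)
    inside = shapely.intersects(poly, pts)
    if not inside.any():
        warnings.warn("ROI encloses no points", stacklevel=2)
    return cloud.subset(inside)


def geo_to_pixel(
    coords: np.ndarray,
    origin: tuple[float, float],
    resolution_cm: float,
) -> np.ndarray:
    """Map geo-coordinates (metres) to integer pixel (row, col) indices.

    The origin is the geo-position of the upper-left raster corner; row 0 is
    the northern edge and rows grow southward (decreasing y).  Pixel centres
    sit at half-integer offsets from the origin.
    """
    if resolution_cm <= 0:
        raise ValueError("resolution must be positive")
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    # work in centimetres so whole-cm geo offsets divide exactly
    col = np.floor((coords[:, 0] - origin[0]) * 100.0 / resolution_cm).astype(np.int64)
    row = np.floor((origin[1] - coords[:, 1]) * 100.0 / resolution_cm).astype(np.int64)
    out = np.column_stack([row, col])
    return out[0] if out.shape[0] == 1 else out


def pixel_to_geo(
    pixels: np.ndarray,
    origin: tuple[float, float],
    resolution_cm: float,
) -> np.ndarray:
    """Map (row, col) pixel indices to the geo-coordinates of pixel centres."""
    if resolution_cm <= 0:
        raise ValueError("resolution must be positive")
    pixels = np.atleast_2d(np.asarray(pixels, dtype=np.float64))
    res_m = resolution_cm / 100.0
    gx = origin[0] + (pixels[:, 1] + 0.5) * res_m
    gy = origin[1] - (pixels[:, 0] + 0.5) * res_m
    out = np.column_stack([gx, gy])
    return out[0] if out.shape[0] == 1 else out
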