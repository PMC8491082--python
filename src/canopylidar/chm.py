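"""Canopy height model: DSM rasterization, grayscale encoding, and
four-marker perspective alignment.

The CHM is a 2D grid of canopy heights (cm) at a fixed cm-per-pixel
resolution (default 1 cm/pixel) built by TIN interpolation of the normalized
above-ground points.  Heights are encoded to 8-bit grayscale with a linear
calibration: 0 cm is black and 160 cm is white by default; taller points map
to higher intensities, clamped at the ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from skimage.transform import ProjectiveTransform, warp

from .cloudio import ABOVE_GROUND, PointCloud
from .preprocess import tin_interpolate

__all__ = ["CHMRaster", "GrayEncoding", "rasterize_chm", "encode_grayscale",
           "decode_grayscale", "align_perspective"]


@dataclass
class CHMRaster:
    """Gridded canopy height model.

    ``heights`` holds canopy height in cm with NaN where no data; ``valid``
    is the matching data mask.  ``origin`` is the geo-coordinate (metres) of
    the upper-left raster corner; row 0 is the northern edge.
    """

    heights: np.ndarray
    resolution_cm: float
    origin: tuple[float, float]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.resolution_cm <= 0:
            raise ValueError("resolution must be positive")
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if self.valid is None:
            self.valid = np.isfinite(self.heights)
        with np.errstate(invalid="ignore"):
            if np.any(self.heights[self.valid] < 0):
                raise ValueError("CHM heights must be >= 0 where data present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape


@dataclass(frozen=True)
class GrayEncoding:
    """Linear height-to-intensity calibration: ``h_black`` cm maps to 0 and
    ``h_white`` cm to 255."""

    h_black: float = 0.0
    h_white: float = 160.0

    def __post_init__(self) -> None:
        if self.h_white <= self.h_black:
            raise ValueError("h_white must exceed h_black")


def rasterize_chm(
    above_ground: PointCloud,
    resolution_cm: float = 1.0,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
    max_edge: float = 0.2,
) -> CHMRaster:
    """Build the CHM from a normalized cloud (ground at 0, heights in cm).

    Cell values are TIN-interpolated canopy heights at cell centres; regions
    with no canopy (outside the point hull, or spanned only by triangles with
    an edge longer than ``max_edge`` metres, e.g. inter-plot gaps) are
    no-data.
    """
    pts = above_ground
    if pts.classification is not None:
        above = pts.classification == ABOVE_GROUND
        if above.any():
            pts = pts.subset(above)
    if len(pts) == 0:
        warnings.warn("no above-ground points; CHM is all no-data", stacklevel=2)
        if shape is None or origin is None:
            raise ValueError("empty cloud needs an explicit origin and shape")
        return CHMRaster(np.full(shape, np.nan), resolution_cm, origin)
    raster, used_origin = tin_interpolate(
        pts, resolution_cm, origin=origin, shape=shape, max_edge=max_edge
    )
    np.clip(raster, 0.0, None, out=raster)
    return CHMRaster(raster, resolution_cm, used_origin)


def encode_grayscale(chm: CHMRaster, enc: GrayEncoding = GrayEncoding()) -> np.ndarray:
    """Encode CHM heights to 8-bit grayscale.

    intensity = round_half_up(255 * (h - h_black) / (h_white - h_black)),
    clamped to [0, 255]; no-data cells encode as 0 (the validity mask stays on
    the raster object).
    """
    scaled = 255.0 * (chm.heights - enc.h_black) / (enc.h_white - enc.h_black)
    with np.errstate(invalid="ignore"):
        intensity = np.clip(np.floor(scaled + 0.5), 0, 255)
    intensity = np.where(chm.valid, intensity, 0.0)
    return intensity.astype(np.uint8)


def decode_grayscale(image: np.ndarray, enc: GrayEncoding = GrayEncoding()) -> np.ndarray:
    """Inverse of :func:`encode_grayscale` up to the 8-bit quantization step
    ((h_white - h_black) / 255 cm)."""
    return image.astype(np.float64) * (enc.h_white - enc.h_black) / 255.0 + enc.h_black


def _edge_lengths(corners: np.ndarray) -> tuple[float, float]:
    """Mean opposing edge lengths (width, height) of a UL,UR,LL,LR quad."""
    ul, ur, ll, lr = corners
    width = (np.linalg.norm(ur - ul) + np.linalg.norm(lr - ll)) / 2.0
    height = (np.linalg.norm(ll - ul) + np.linalg.norm(lr - ur)) / 2.0
    return width, height


def align_perspective(image: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Warp the marker quadrilateral to an axis-aligned rectangle.

    ``markers`` is a 4 x 2 array of (col, row) pixel positions in the order
    upper-left, upper-right, lower-left, lower-right.  The output rectangle's
    width and height are the means of the opposing marker-edge lengths,
    rounded to pixels.
    """
    corners = np.asarray(markers, dtype=np.float64)
    if corners.shape != (4, 2):
        raise ValueError("markers must be a 4x2 array (UL, UR, LL, LR)")
    ul, ur, ll, lr = corners
    # ring UL->UR->LR->LL must be simple with positive area
    ring = np.array([ul, ur, lr, ll])
    if not shapely.Polygon(ring).is_valid or shapely.Polygon(ring).area <= 0:
        raise ValueError("marker order is self-intersecting or degenerate")
    width, height = _edge_lengths(corners)
    out_w, out_h = int(round(width)), int(round(height))
    dst = np.array([[0, 0], [out_w, 0], [0, out_h], [out_w, out_h]], dtype=np.float64)
    tform = ProjectiveTransform.from_estimate(dst, corners)
    if not tform:
        raise ValueError("could not estimate perspective transform")
    out = warp(image.astype(np.float64), tform, output_shape=(out_h, out_w), order=1,
               mode="constant", cval=0.0, preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.round(out), 0, np.iinfo(image.dtype).max).astype(image.dtype)
    return out
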