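"""Plot segmentation of the aligned CHM image.

Stages: threshold the CHM into a canopy mask (global Otsu OR-combined with a
local Sauvola threshold, so a non-uniform background still segments), detect
near-axis-parallel gap lines per orientation with a Sobel + Hough transform,
merge lines that describe the same inter-plot gap, assemble the line lattice
into plot rectangles (optionally assisted by evenly spaced layout baselines),
snap each rectangle to the canopy content inside its lattice cell, and refine
a per-plot sampling window at the entropy-weighted centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter, uniform_filter1d
from skimage.filters import rank, sobel_h, sobel_v, threshold_otsu, threshold_sauvola
from skimage.morphology import footprint_rectangle, remove_small_holes, remove_small_objects
from skimage.transform import hough_line, hough_line_peaks

from .synthfield import FieldLayout

__all__ = [
    "SegmentationParams",
    "Line",
    "PlotRecord",
    "PlotGrid",
    "binarize_canopy",
    "detect_plot_lines",
    "merge_lines",
    "build_plot_masks",
    "refine_plot_window",
    "segment_plots",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the segmentation stage.

    ``merge_distance`` (pixels) defaults to the inter-plot gap at 1 cm/pixel
    plus the ~2 px width of the Sobel edge response on each side (35): lines
    within one gap width describe one gap.  ``min_line_votes`` is
    the Hough peak threshold as a fraction of the mask dimension a line spans.
    ``entropy_window`` (pixels) sizes the local-entropy neighbourhood of the
    sampling-window refinement and ``refine_margin`` the per-side shrink
    fraction.
    """

    merge_distance: float = 35.0
    min_line_votes: float = 0.3
    entropy_window: int = 9
    refine_margin: float = 0.10
    angle_tolerance_deg: float = 2.0
    line_smooth: int = 51

    def __post_init__(self) -> None:
        if self.merge_distance <= 0:
            raise ValueError("merge_distance must be positive")
        if not 0 < self.min_line_votes <= 1:
            raise ValueError("min_line_votes must be a fraction in (0, 1]")


@dataclass(frozen=True)
class Line:
    """An axis-near line: ``intercept`` is the column (vertical lines) or row
    (horizontal lines) where it crosses the image, ``votes`` its Hough
    support."""

    intercept: float
    votes: float
    orientation: str


@dataclass
class PlotRecord:
    row_id: int
    col_id: int
    rect: tuple[int, int, int, int]  # x0, y0, x1, y1 in pixels, exclusive end
    refined: tuple[int, int, int, int] | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PlotGrid:
    plots: list[PlotRecord]
    n_rows: int
    n_cols: int

    def __len__(self) -> int:
        return len(self.plots)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self.plots:
            ref = p.refined if p.refined is not None else (np.nan,) * 4
            rows.append((p.row_id, p.col_id, *p.rect, *ref, ";".join(p.flags)))
        return pd.DataFrame(
            rows,
            columns=["row_id", "col_id", "x0", "y0", "x1", "y1",
                     "rx0", "ry0", "rx1", "ry1", "flags"],
        )


def binarize_canopy(chm_image: np.ndarray, window: int = 51) -> np.ndarray:
    """Initial canopy mask: pixelwise OR of a global (Otsu) and a local
    adaptive (Sauvola) threshold, restricted to pixels with data (> 0)."""
    img = np.asarray(chm_image, dtype=np.float64)
    valid = img > 0
    if img.max() == img.min():
        warnings.warn("constant CHM image; empty canopy mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    global_t = threshold_otsu(img)
    local_t = threshold_sauvola(img, window_size=window)
    # the local threshold rescues canopy under a drifting background, but on a
    # near-constant window it sits just below the window's own level and would
    # admit flat background wholesale; gate it on genuine local contrast
    m = uniform_filter(img, window)
    s = np.sqrt(np.maximum(uniform_filter(img * img, window) - m * m, 0.0))
    local_mask = (img > local_t) & (s > 2.0)
    mask = valid & ((img > global_t) | local_mask)
    if not mask.any():
        warnings.warn("canopy mask is empty", stacklevel=2)
        return mask
    # within-plot holes (interpolation dropouts, sampled plants) and isolated
    # specks in the gaps are both smaller than one gap-width square; cleaning
    # them keeps hole edges from polluting the line detection
    mask = remove_small_objects(mask, max_size=63)
    mask = remove_small_holes(mask, max_size=900)
    return mask


def detect_plot_lines(
    mask: np.ndarray,
    orientation: str,
    params: SegmentationParams = SegmentationParams(),
) -> list[Line]:
    """Detect gap lines of one orientation with Sobel edges + Hough transform.

    Only lines within ``angle_tolerance_deg`` of exactly vertical/horizontal
    are accumulated (the CHM is aligned beforehand), and peaks must gather at
    least ``min_line_votes`` x the spanned mask dimension.  Before edge
    detection the mask is smoothed *along* the candidate line direction
    (``line_smooth`` window): a ragged plot boundary wiggles a few pixels
    across rows, which dilutes Hough votes over neighbouring columns;
    averaging along the line re-centres the boundary without moving it.
    """
    if orientation not in ("horizontal", "vertical"):
        raise ValueError("orientation must be 'horizontal' or 'vertical'")
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask")
    tol = params.angle_tolerance_deg
    thetas = np.deg2rad(np.linspace(-tol, tol, 9))
    axis = 0 if orientation == "vertical" else 1
    smooth = max(1, min(params.line_smooth, mask.shape[axis]))
    img = uniform_filter1d(mask.astype(np.float64), smooth, axis=axis,
                           mode="nearest")
    # a ragged edge smears the smoothed transition over a few pixels; a low
    # gradient threshold keeps every column of the transition band voting
    if orientation == "vertical":
        edges = np.abs(sobel_v(img)) > 0.1
        span = mask.shape[0]
    else:
        edges = np.abs(sobel_h(img)) > 0.1
        thetas = thetas + np.pi / 2.0
        span = mask.shape[1]
    accum, angles, dists = hough_line(edges, theta=thetas)
    vote_floor = params.min_line_votes * span
    peaks = hough_line_peaks(
        accum, angles, dists,
        min_distance=2, min_angle=1,
        threshold=vote_floor, num_peaks=500,
    )
    # canonicalize each peak to its crossing of the image centre line: a
    # slightly tilted peak's rho is offset by up to centre * sin(theta)
    cy, cx = (np.asarray(mask.shape) - 1) / 2.0
    lines = []
    for votes, theta, rho in zip(*peaks):
        if votes < vote_floor:
            continue
        if orientation == "vertical":
            intercept = (rho - cy * np.sin(theta)) / np.cos(theta)
        else:
            intercept = (rho - cx * np.cos(theta)) / np.sin(theta)
        lines.append(Line(float(intercept), float(votes), orientation))
    return sorted(lines, key=lambda ln: ln.intercept)


def merge_lines(lines: list[Line], merge_distance: float) -> list[Line]:
    """Collapse chains of lines whose neighbouring intercepts differ by at
    most ``merge_distance`` into single lines at the vote-weighted mean."""
    if not lines:
        return []
    orientations = {ln.orientation for ln in lines}
    if len(orientations) > 1:
        raise ValueError("all lines must share one orientation")
    ordered = sorted(lines, key=lambda ln: ln.intercept)
    merged: list[Line] = []
    group = [ordered[0]]
    for ln in ordered[1:]:
        if ln.intercept - group[-1].intercept <= merge_distance:
            group.append(ln)
        else:
            merged.append(_weighted_line(group))
            group = [ln]
    merged.append(_weighted_line(group))
    return merged


def _weighted_line(group: list[Line]) -> Line:
    votes = np.array([ln.votes for ln in group])
    intercepts = np.array([ln.intercept for ln in group])
    total = votes.sum()
    centre = float((intercepts * votes).sum() / total) if total else float(intercepts.mean())
    return Line(centre, float(total), group[0].orientation)


def _snap_interval(profile: np.ndarray, threshold: float = 0.5) -> tuple[int, int] | None:
    """First/last index of a profile at or above threshold, as a half-open
    interval; None when nothing qualifies."""
    hits = np.flatnonzero(profile >= threshold)
    if hits.size == 0:
        return None
    return int(hits[0]), int(hits[-1]) + 1


def _baselines(extent: tuple[int, int], n_plots: int) -> list[Line]:
    lo, hi = extent
    positions = np.linspace(lo, hi, n_plots + 1)
    return [Line(float(p), 0.0, "baseline") for p in positions]


def _cell_occupancy(ys: list[float], xs: list[float], mask: np.ndarray) -> np.ndarray:
    """Mean mask occupancy of every lattice cell."""
    occ = np.zeros((len(ys) - 1, len(xs) - 1))
    for i in range(len(ys) - 1):
        y0, y1 = max(int(round(ys[i])), 0), int(round(ys[i + 1]))
        for j in range(len(xs) - 1):
            x0, x1 = max(int(round(xs[j])), 0), int(round(xs[j + 1]))
            if y1 > y0 and x1 > x0:
                occ[i, j] = mask[y0:y1, x0:x1].mean()
    return occ


# a lattice slab whose best cell holds less canopy than this is an inter-plot
# gap sliver (possibly fringed by eroded plot edges), not a plot
_SLAB_OCCUPANCY = 0.4


def build_plot_masks(
    hlines: list[Line],
    vlines: list[Line],
    layout: FieldLayout | None = None,
    mask: np.ndarray | None = None,
) -> PlotGrid:
    """Assemble merged gap lines into plot rectangles.

    Candidate rectangles are the cells of the line lattice.  When ``mask`` is
    given, lattice slabs (row/column intervals) whose cells hold essentially
    no canopy are classified as inter-plot gaps and dropped - an imperfectly
    merged gap contributes a sliver cell, not a plot - and each surviving
    cell is snapped to the canopy occupancy inside it (occupancy >= 0.5 along
    each axis), recovering the plot edges rather than the gap centres.
    When a layout is supplied and the resulting plot-slab count disagrees
    with it, evenly spaced baselines over the mask content replace the
    deficient orientation.  Row/column ids are 0-based from the top-left.
    """
    if len(hlines) < 2 or len(vlines) < 2:
        if layout is None or mask is None:
            raise ValueError(
                "need at least 2 lines per orientation (or a layout with a mask)"
            )
    ys = sorted(ln.intercept for ln in hlines)
    xs = sorted(ln.intercept for ln in vlines)

    if mask is None:
        # pure lattice: every cell is a plot
        plots = [
            PlotRecord(i, j, (int(round(xs[j])), int(round(ys[i])),
                              int(round(xs[j + 1])), int(round(ys[i + 1]))))
            for i in range(len(ys) - 1) for j in range(len(xs) - 1)
        ]
        return PlotGrid(plots, len(ys) - 1, len(xs) - 1)

    def content_extent(axis: int) -> tuple[int, int]:
        hit = np.flatnonzero(mask.any(axis=axis))
        return (int(hit[0]), int(hit[-1]) + 1) if hit.size else (0, mask.shape[1 - axis])

    def classify(ys, xs):
        occ = _cell_occupancy(ys, xs, mask)
        return occ, occ.max(axis=1) >= _SLAB_OCCUPANCY, occ.max(axis=0) >= _SLAB_OCCUPANCY

    if len(ys) >= 2 and len(xs) >= 2:
        occ, row_is_plot, col_is_plot = classify(ys, xs)
    else:
        occ = np.zeros((0, 0))
        row_is_plot = np.zeros(max(len(ys) - 1, 0), dtype=bool)
        col_is_plot = np.zeros(max(len(xs) - 1, 0), dtype=bool)

    if layout is not None:
        if int(row_is_plot.sum()) != layout.n_plot_rows:
            ys = sorted(ln.intercept for ln in _baselines(content_extent(1), layout.n_plot_rows))
        if int(col_is_plot.sum()) != layout.n_plot_cols:
            xs = sorted(ln.intercept for ln in _baselines(content_extent(0), layout.n_plot_cols))
        occ, row_is_plot, col_is_plot = classify(ys, xs)

    plots: list[PlotRecord] = []
    row_ids = np.cumsum(row_is_plot) - 1
    col_ids = np.cumsum(col_is_plot) - 1
    for i in range(len(ys) - 1):
        if not row_is_plot[i]:
            continue
        for j in range(len(xs) - 1):
            if not col_is_plot[j]:
                continue
            y0, y1 = max(int(round(ys[i])), 0), int(round(ys[i + 1]))
            x0, x1 = max(int(round(xs[j])), 0), int(round(xs[j + 1]))
            flags: list[str] = []
            cell = mask[y0:y1, x0:x1]
            ci = _snap_interval(cell.mean(axis=0)) if cell.size else None
            ri = _snap_interval(cell.mean(axis=1)) if cell.size else None
            if ci is not None and ri is not None:
                x0, x1 = x0 + ci[0], x0 + ci[1]
                y0, y1 = y0 + ri[0], y0 + ri[1]
            else:
                flags.append("no_content")
            plots.append(PlotRecord(int(row_ids[i]), int(col_ids[j]),
                                    (x0, y0, x1, y1), flags=flags))
    return PlotGrid(plots, int(row_is_plot.sum()), int(col_is_plot.sum()))


def local_entropy(image: np.ndarray, window: int) -> np.ndarray:
    """Grayscale entropy (bits) of each pixel's window neighbourhood."""
    img8 = np.asarray(image, dtype=np.uint8)
    return rank.entropy(img8, footprint_rectangle((window, window)))


def refine_plot_window(
    chm_image: np.ndarray,
    rect: tuple[int, int, int, int],
    entropy_window: int = 9,
    margin: float = 0.10,
) -> tuple[tuple[int, int, int, int], list[str]]:
    """Shrink a plot rectangle by ``margin`` per side and re-centre it at the
    entropy-weighted centroid of the plot's texture, clipped to the plot.

    Uniform or empty plots fall back to the geometric centre (flagged for the
    empty case).
    """
    x0, y0, x1, y1 = rect
    flags: list[str] = []
    sub = np.asarray(chm_image)[y0:y1, x0:x1]
    h, w = sub.shape
    if h == 0 or w == 0:
        raise ValueError("rectangle lies outside the image")
    if not np.any(sub):
        flags.append("empty_plot")
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        ent = local_entropy(sub, entropy_window).astype(np.float64)
        total = ent.sum()
        if total == 0:
            cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        else:
            yy, xx = np.mgrid[0:h, 0:w]
            cy = float((ent * yy).sum() / total)
            cx = float((ent * xx).sum() / total)
    new_w = max(1, int(round(w * (1 - 2 * margin))))
    new_h = max(1, int(round(h * (1 - 2 * margin))))
    rx0 = int(round(cx - new_w / 2.0))
    ry0 = int(round(cy - new_h / 2.0))
    rx0 = min(max(rx0, 0), w - new_w)
    ry0 = min(max(ry0, 0), h - new_h)
    return (x0 + rx0, y0 + ry0, x0 + rx0 + new_w, y0 + ry0 + new_h), flags


def _with_boundary_lines(lines: list[Line], mask: np.ndarray, axis: int,
                         merge_distance: float, orientation: str) -> list[Line]:
    """Add field-boundary lines at the mask content extent when no detected
    line is near it (a plot flush with the raster border has no gap edge
    there to detect)."""
    hit = np.flatnonzero(mask.any(axis=axis))
    if hit.size == 0:
        return lines
    out = list(lines)
    for edge in (float(hit[0]), float(hit[-1]) + 1):
        if not any(abs(ln.intercept - edge) <= merge_distance for ln in out):
            out.append(Line(edge, 0.0, orientation))
    return sorted(out, key=lambda ln: ln.intercept)


def segment_plots(
    chm_image: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    layout: FieldLayout | None = None,
) -> PlotGrid:
    """Full segmentation stage: binarize, detect + merge lines per
    orientation (plus field-boundary lines at the content extent), build the
    plot lattice, and refine sampling windows."""
    mask = binarize_canopy(chm_image)
    try:
        h = merge_lines(detect_plot_lines(mask, "horizontal", params), params.merge_distance)
        v = merge_lines(detect_plot_lines(mask, "vertical", params), params.merge_distance)
        h = _with_boundary_lines(h, mask, 1, params.merge_distance, "horizontal")
        v = _with_boundary_lines(v, mask, 0, params.merge_distance, "vertical")
    except ValueError:
        if layout is None:
            raise
        h, v = [], []
    grid = build_plot_masks(h, v, layout=layout, mask=mask)
    for plot in grid.plots:
        plot.refined, flags = refine_plot_window(
            chm_image, plot.rect, params.entropy_window, params.refine_margin
        )
        plot.flags.extend(flags)
    return grid
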