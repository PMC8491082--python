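"""Plot segmentation: thresholding, line detection/merging, lattice
assembly, and entropy-based sampling-window refinement."""

import numpy as np
import pytest

from canopylidar.plotseg import (
    Line,
    SegmentationParams,
    binarize_canopy,
    build_plot_masks,
    detect_plot_lines,
    merge_lines,
    refine_plot_window,
    segment_plots,
)
from canopylidar.synthfield import FieldLayout


def grid_image(n_rows=3, n_cols=3, plot=(120, 200), gap=30, margin=40,
               fg=120, bg=5, noise_seed=None):
    """Synthetic CHM image of a plot grid (intensity fg) on background bg."""
    ph, pw = plot
    h = 2 * margin + n_rows * ph + (n_rows - 1) * gap
    w = 2 * margin + n_cols * pw + (n_cols - 1) * gap
    img = np.full((h, w), bg, dtype=np.uint8)
    rects = []
    for i in range(n_rows):
        for j in range(n_cols):
            y0 = margin + i * (ph + gap)
            x0 = margin + j * (pw + gap)
            img[y0:y0 + ph, x0:x0 + pw] = fg
            rects.append((x0, y0, x0 + pw, y0 + ph))
    if noise_seed is not None:
        r = np.random.default_rng(noise_seed)
        img = np.clip(img.astype(int) + r.integers(-3, 4, img.shape), 0, 255).astype(np.uint8)
    return img, rects


class TestBinarize:
    def test_plots_recovered_on_uniform_background(self):
        img, rects = grid_image()
        mask = binarize_canopy(img)
        plot_px = np.zeros_like(mask)
        for x0, y0, x1, y1 in rects:
            plot_px[y0:y1, x0:x1] = True
        assert mask[plot_px].mean() >= 0.99
        assert mask[~plot_px].mean() <= 0.01

    def test_constant_image_warns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize_canopy(np.full((50, 50), 7, dtype=np.uint8))
        assert not mask.any()

    def test_intensity_gradient_background(self):
        img, rects = grid_image(fg=120, bg=5)
        ramp = np.linspace(0, 40, img.shape[1])[None, :]
        img = np.clip(img + ramp, 0, 255).astype(np.uint8)
        mask = binarize_canopy(img)
        for x0, y0, x1, y1 in rects:
            assert mask[y0:y1, x0:x1].mean() >= 0.95


class TestDetectLines:
    def test_three_by_three_grid_gap_lines(self):
        img, rects = grid_image()
        mask = binarize_canopy(img)
        params = SegmentationParams()
        for orient, idx in (("vertical", 0), ("horizontal", 1)):
            lines = merge_lines(detect_plot_lines(mask, orient, params),
                                params.merge_distance)
            assert len(lines) == 4
            # inner merged lines sit at the gap centres
            if orient == "vertical":
                expected = [40, 255, 485, 700]  # outer edges + gap centres
            else:
                expected = [40, 175, 325, 460]
            for ln, e in zip(lines, expected):
                assert abs(ln.intercept - e) <= 3

    def test_single_rectangle_two_lines_each(self):
        img = np.zeros((200, 300), dtype=np.uint8)
        img[50:150, 60:240] = 150
        mask = binarize_canopy(img)
        for orient in ("vertical", "horizontal"):
            assert len(detect_plot_lines(mask, orient)) >= 2
            merged = merge_lines(detect_plot_lines(mask, orient), 35)
            assert len(merged) == 2

    def test_diagonal_stripes_no_axis_lines(self):
        yy, xx = np.mgrid[0:300, 0:300]
        mask = ((xx + yy) // 30) % 2 == 0
        for orient in ("vertical", "horizontal"):
            assert detect_plot_lines(mask, orient) == []

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_plot_lines(np.zeros((10, 10), bool), "vertical")


class TestMergeLines:
    def test_close_lines_collapse_to_weighted_mean(self):
        lines = [Line(100.0, 30.0, "vertical"), Line(102.0, 10.0, "vertical")]
        merged = merge_lines(lines, 5.0)
        assert len(merged) == 1
        assert merged[0].intercept == pytest.approx((100 * 30 + 102 * 10) / 40)

    def test_distant_lines_unchanged(self):
        lines = [Line(100.0, 1.0, "v"), Line(200.0, 1.0, "v")]
        assert [ln.intercept for ln in merge_lines(lines, 5.0)] == [100.0, 200.0]

    def test_empty_input(self):
        assert merge_lines([], 5.0) == []

    def test_mixed_orientations_rejected(self):
        with pytest.raises(ValueError):
            merge_lines([Line(0, 1, "vertical"), Line(1, 1, "horizontal")], 5)


class TestBuildPlotMasks:
    def test_synthetic_grid_rectangles_within_3px(self):
        img, rects = grid_image(noise_seed=3)
        grid = segment_plots(img)
        assert len(grid) == 9
        for p, (x0, y0, x1, y1) in zip(grid.plots, rects):
            gx0, gy0, gx1, gy1 = p.rect
            assert max(abs(gx0 - x0), abs(gy0 - y0), abs(gx1 - x1), abs(gy1 - y1)) <= 3

    @pytest.mark.parametrize("seed", range(5))
    def test_boundaries_within_3px_across_seeds(self, seed):
        img, rects = grid_image(noise_seed=seed)
        grid = segment_plots(img)
        assert len(grid) == 9
        errs = [
            max(abs(p.rect[0] - r[0]), abs(p.rect[1] - r[1]),
                abs(p.rect[2] - r[2]), abs(p.rect[3] - r[3]))
            for p, r in zip(grid.plots, rects)
        ]
        assert max(errs) <= 3

    def test_degraded_gaps_with_layout(self):
        img, rects = grid_image()
        r = np.random.default_rng(0)
        # fill 40% of gap pixels with canopy intensity (e.g. lodging)
        plot_px = np.zeros(img.shape, bool)
        for x0, y0, x1, y1 in rects:
            plot_px[y0:y1, x0:x1] = True
        gap_px = np.argwhere(~plot_px)
        chosen = gap_px[r.random(len(gap_px)) < 0.4]
        img[chosen[:, 0], chosen[:, 1]] = 120
        layout = FieldLayout(n_plot_rows=3, n_plot_cols=3)
        grid = segment_plots(img, layout=layout)
        assert len(grid) == 9

    def test_layout_always_gives_full_count(self):
        # only one orientation detectable: a single row of plots
        img, _ = grid_image(n_rows=1, n_cols=3)
        grid = segment_plots(img, layout=FieldLayout(n_plot_rows=1, n_plot_cols=3))
        assert len(grid) == 3 and grid.n_rows == 1 and grid.n_cols == 3

    def test_too_few_lines_without_layout_rejected(self):
        with pytest.raises(ValueError):
            build_plot_masks([Line(0, 1, "h")], [Line(0, 1, "v")])

    def test_intensity_offset_invariance(self):
        img, _ = grid_image(noise_seed=1)
        grid_a = segment_plots(img)
        shifted = np.clip(img.astype(int) + 20, 0, 255).astype(np.uint8)
        grid_b = segment_plots(shifted)
        assert len(grid_a) == len(grid_b) == 9
        for pa, pb in zip(grid_a.plots, grid_b.plots):
            assert max(abs(a - b) for a, b in zip(pa.rect, pb.rect)) <= 2


class TestRefineWindow:
    def test_uniform_plot_centres_window(self, rng):
        img = rng.integers(100, 140, (100, 200)).astype(np.uint8)
        refined, flags = refine_plot_window(img, (0, 0, 200, 100), margin=0.1)
        x0, y0, x1, y1 = refined
        assert flags == []
        assert abs((x0 + x1) / 2 - 100) <= 2
        assert abs((y0 + y1) / 2 - 50) <= 2
        assert (x1 - x0, y1 - y0) == (160, 80)

    def test_left_texture_shifts_centroid_matches_oracle(self, rng):
        img = np.full((60, 120), 100, dtype=np.uint8)
        img[:, :60] = rng.integers(60, 200, (60, 60)).astype(np.uint8)
        # a wide margin keeps the refined window unclipped at the plot edge
        refined, _ = refine_plot_window(img, (0, 0, 120, 60), entropy_window=9,
                                        margin=0.3)
        from canopylidar.plotseg import local_entropy

        ent = local_entropy(img, 9).astype(float)
        # brute-force weighted centroid of the entropy map
        yy, xx = np.mgrid[0:60, 0:120]
        cx = (ent * xx).sum() / ent.sum()
        x0, x1 = refined[0], refined[2]
        assert abs((x0 + x1) / 2 - cx) <= 1 + 0.5  # rounding
        assert (x0 + x1) / 2 < 60  # clearly shifted left of centre

    def test_entropy_map_matches_brute_force(self):
        r = np.random.default_rng(1)
        img = r.integers(0, 8, (20, 20)).astype(np.uint8)
        from canopylidar.plotseg import local_entropy

        ent = local_entropy(img, 3)
        # interior pixels: explicit histogram entropy over the 3x3 window
        for y in range(1, 19):
            for x in range(1, 19):
                window = img[y - 1:y + 2, x - 1:x + 2]
                _, counts = np.unique(window, return_counts=True)
                p = counts / counts.sum()
                expected = -(p * np.log2(p)).sum()
                assert ent[y, x] == pytest.approx(expected, abs=1e-6)

    def test_all_zero_plot_falls_back_flagged(self):
        img = np.zeros((50, 80), dtype=np.uint8)
        refined, flags = refine_plot_window(img, (0, 0, 80, 50))
        assert "empty_plot" in flags
        x0, y0, x1, y1 = refined
        assert abs((x0 + x1) / 2 - 40) <= 1 and abs((y0 + y1) / 2 - 25) <= 1
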