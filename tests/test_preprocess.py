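"""Denoising against a brute-force oracle, ground classification on
generator truth, terrain flattening, and TIN interpolation."""

import numpy as np
import pytest

from canopylidar.cloudio import ABOVE_GROUND, GROUND, PointCloud
from canopylidar.preprocess import (
    DenoiseParams,
    GroundFilterParams,
    classify_ground,
    denoise,
    normalize_heights,
    tin_interpolate,
)
from canopylidar.synthfield import CanopySpec, FieldLayout, TerrainSpec, generate_field


def brute_force_outliers(xyz, n_neighbors, k):
    """O(n^2) statistical outlier removal, no spatial index."""
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    d_sorted = np.sort(d, axis=1)[:, 1:n_neighbors + 1]
    mean_d = d_sorted.mean(axis=1)
    return mean_d > mean_d.mean() + k * mean_d.std()


class TestDenoise:
    def test_regular_grid_matches_brute_force(self):
        g = np.mgrid[0:10, 0:10, 0:1].reshape(3, -1).T.astype(float)
        cloud = PointCloud(g[:, 0], g[:, 1], g[:, 2])
        params = DenoiseParams(n_neighbors=8, k=1.0)
        clean, outl = denoise(cloud, params)
        expected = brute_force_outliers(g, 8, 1.0)
        assert len(outl) == int(expected.sum())
        got = np.zeros(len(cloud), dtype=bool)
        got_set = {tuple(p) for p in outl.xyz}
        for i, p in enumerate(g):
            got[i] = tuple(p) in got_set
        np.testing.assert_array_equal(got, expected)

    def test_distant_point_flagged(self):
        g = np.mgrid[0:10, 0:10, 0:1].reshape(3, -1).T.astype(float)
        g = np.vstack([g, [500.0, 500.0, 0.0]])
        cloud = PointCloud(g[:, 0], g[:, 1], g[:, 2])
        clean, outl = denoise(cloud, DenoiseParams(n_neighbors=8))
        assert any(np.allclose(p, [500, 500, 0]) for p in outl.xyz)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_clouds_match_brute_force(self, seed):
        r = np.random.default_rng(seed)
        n = r.integers(300, 1200)
        xyz = r.uniform(0, 10, (n, 3))
        cloud = PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        params = DenoiseParams(n_neighbors=12, k=1.0)
        _, outl = denoise(cloud, params)
        expected = brute_force_outliers(xyz, 12, 1.0)
        assert len(outl) == int(expected.sum())

    def test_reapplication_flags_no_more(self):
        r = np.random.default_rng(3)
        xyz = r.uniform(0, 5, (800, 3))
        cloud = PointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2])
        params = DenoiseParams(n_neighbors=10)
        clean1, out1 = denoise(cloud, params)
        clean2, out2 = denoise(clean1, params)
        assert len(out2) <= len(out1)

    def test_too_small_cloud_rejected(self):
        cloud = PointCloud(np.arange(5.0), np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError, match="too small"):
            denoise(cloud, DenoiseParams(n_neighbors=10))

    def test_for_density_preserves_radius(self):
        p = DenoiseParams.for_density(15000.0)
        assert p.n_neighbors == pytest.approx(50, abs=2)
        assert DenoiseParams.for_density(1500.0).n_neighbors < 10


class TestClassifyGround:
    def test_bare_terrain_all_ground(self):
        terrain = TerrainSpec(slope_x=0.02, ground_roughness_sd=0.3)
        cloud, _ = generate_field(FieldLayout(), CanopySpec(mean_height=0.0), terrain, 5)
        labeled = classify_ground(cloud)
        assert (labeled.classification == GROUND).mean() >= 0.99

    def test_canopy_block_separated(self):
        cloud, _ = generate_field(
            FieldLayout(), CanopySpec(mean_height=80.0, height_sd=0.0), TerrainSpec(), 6
        )
        truth = cloud.classification.copy()
        labeled = classify_ground(cloud)
        g, a = truth == GROUND, truth == ABOVE_GROUND
        assert (labeled.classification[g] == GROUND).mean() >= 0.99
        assert (labeled.classification[a] == ABOVE_GROUND).mean() >= 0.99

    def test_single_point_is_ground(self):
        labeled = classify_ground(PointCloud([1.0], [2.0], [3.0]))
        assert labeled.classification[0] == GROUND

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            classify_ground(PointCloud([], [], []))


class TestNormalizeHeights:
    def test_sloped_bare_ground_flattens_below_1cm(self):
        terrain = TerrainSpec(slope_x=0.035)  # ~2 degrees
        cloud, _ = generate_field(FieldLayout(), CanopySpec(mean_height=0.0), terrain, 8)
        norm = normalize_heights(classify_ground(cloud))
        assert np.abs(norm.z).max() <= 1.0  # cm

    def test_uniform_canopy_on_slope_recovered(self):
        terrain = TerrainSpec(slope_x=0.035)
        spec = CanopySpec(mean_height=80.0, height_sd=0.0, row_relief_cm=0.0)
        cloud, _ = generate_field(FieldLayout(), spec, terrain, 9)
        norm = normalize_heights(classify_ground(cloud))
        above = norm.z[norm.classification == ABOVE_GROUND]
        assert above.size > 0
        assert np.abs(above - 80.0).max() <= 2.0

    def test_flat_offset_ground_exactly_zero(self):
        r = np.random.default_rng(0)
        cloud = PointCloud(r.uniform(0, 5, 2000), r.uniform(0, 5, 2000),
                           np.full(2000, 5.0))
        norm = normalize_heights(classify_ground(cloud))
        np.testing.assert_array_equal(norm.z[norm.classification == GROUND], 0.0)

    def test_idempotent(self):
        cloud, _ = generate_field(
            FieldLayout(), CanopySpec(height_sd=2.0), TerrainSpec(slope_x=0.02), 10
        )
        once = normalize_heights(classify_ground(cloud))
        twice = normalize_heights(once)
        np.testing.assert_allclose(twice.z, once.z, atol=1e-6)

    def test_no_ground_points_rejected(self):
        cloud = PointCloud([0.0, 1.0], [0.0, 1.0], [1.0, 1.0],
                           [ABOVE_GROUND, ABOVE_GROUND])
        with pytest.raises(ValueError, match="no ground"):
            normalize_heights(cloud)

    def test_h10_recovery_within_2cm_rmse(self):
        errors = []
        for seed in range(10):
            spec = CanopySpec(mean_height=80.0, height_sd=3.0, point_density=800.0)
            terrain = TerrainSpec(slope_x=0.035, ground_roughness_sd=0.5,
                                  ground_point_density=400.0)
            cloud, truth = generate_field(FieldLayout(margin=0.5), spec, terrain, seed)
            norm = normalize_heights(classify_ground(cloud))
            row = truth.iloc[0]
            sel = (norm.classification == ABOVE_GROUND) \
                & (norm.x >= row.x0) & (norm.x <= row.x1) \
                & (norm.y >= row.y0) & (norm.y <= row.y1)
            z = np.sort(norm.z[sel])[::-1]
            h10 = z[: int(np.ceil(0.1 * z.size))].mean()
            errors.append(h10 - row.true_h10_cm)
        rmse = float(np.sqrt(np.mean(np.square(errors))))
        assert rmse <= 2.0


class TestTinInterpolate:
    def test_plane_reproduced_exactly(self):
        pts = PointCloud([0.0, 4.0, 0.0], [0.0, 0.0, 4.0],
                         [1.0, 9.0, 13.0])  # z = 2x + 3y + 1
        raster, origin = tin_interpolate(pts, resolution_cm=50.0)
        rows, cols = np.nonzero(np.isfinite(raster))
        res = 0.5
        gx = origin[0] + (cols + 0.5) * res
        gy = origin[1] - (rows + 0.5) * res
        np.testing.assert_allclose(raster[rows, cols], 2 * gx + 3 * gy + 1, atol=1e-6)

    def test_constant_field(self, rng):
        pts = PointCloud(rng.uniform(0, 3, 50), rng.uniform(0, 3, 50),
                         np.full(50, 50.0))
        raster, _ = tin_interpolate(pts, resolution_cm=10.0)
        assert np.nanmax(np.abs(raster - 50.0)) < 1e-9

    def test_matches_brute_force_barycentric(self, rng):
        from scipy.spatial import Delaunay

        xy = rng.uniform(0, 2, (200, 2))
        z = rng.uniform(0, 1, 200)
        pts = PointCloud(xy[:, 0], xy[:, 1], z)
        raster, origin = tin_interpolate(pts, resolution_cm=10.0)
        tri = Delaunay(xy)
        res = 0.1
        for r in range(0, raster.shape[0], 3):
            for c in range(0, raster.shape[1], 3):
                p = np.array([origin[0] + (c + 0.5) * res, origin[1] - (r + 0.5) * res])
                s = tri.find_simplex(p)
                if s < 0:
                    assert np.isnan(raster[r, c])
                    continue
                verts = tri.simplices[s]
                A = np.vstack([xy[verts].T, np.ones(3)])
                w = np.linalg.solve(A, np.array([p[0], p[1], 1.0]))
                np.testing.assert_allclose(raster[r, c], w @ z[verts], atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = PointCloud([0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            tin_interpolate(pts, resolution_cm=10.0)
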