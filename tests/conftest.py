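import numpy as np
import pytest

from canopylidar.cloudio import ABOVE_GROUND, GROUND, PointCloud
from canopylidar.synthfield import CanopySpec, FieldLayout, TerrainSpec, generate_field


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uniform_canopy_cloud(
    rect=(0.0, 0.0, 2.0, 3.0),
    height_cm=80.0,
    n=20000,
    seed=0,
    with_ground=False,
):
    """A normalized plot cloud: canopy points uniform over ``rect`` at a fixed
    height (cm), optionally with ground points at z = 0."""
    r = np.random.default_rng(seed)
    x0, y0, x1, y1 = rect
    x = r.uniform(x0, x1, n)
    y = r.uniform(y0, y1, n)
    z = np.full(n, float(height_cm))
    cls = np.full(n, ABOVE_GROUND, dtype=np.uint8)
    if with_ground:
        gx = r.uniform(x0, x1, n // 2)
        gy = r.uniform(y0, y1, n // 2)
        x = np.concatenate([x, gx])
        y = np.concatenate([y, gy])
        z = np.concatenate([z, np.zeros(n // 2)])
        cls = np.concatenate([cls, np.full(n // 2, GROUND, np.uint8)])
    return PointCloud(x, y, z, cls, z_unit="cm")


@pytest.fixture(scope="session")
def small_field():
    """A 3x3-plot synthetic field with slope, plus its ground truth."""
    layout = FieldLayout(n_plot_rows=3, n_plot_cols=3, margin=0.5)
    spec = CanopySpec(mean_height=80.0, height_sd=3.0)
    terrain = TerrainSpec(slope_x=0.02, slope_y=0.01, ground_roughness_sd=0.3)
    cloud, truth = generate_field(layout, spec, terrain, seed=101)
    return layout, cloud, truth
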