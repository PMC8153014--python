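import numpy as np
import pytest

from peatstack.compositing import (CompositeSpec, mask_clouds,
                                   percentile_range_composite)
from peatstack.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact labelled scene shared by the integration-style tests."""
    config = SceneConfig(rows=80, cols=80, n_optical_dates=8, n_radar_dates=6,
                         cloud_fraction=0.2, seed=11)
    return generate_scene(config, n_polygons_per_class=3, n_points_per_class=20)


@pytest.fixture(scope="session")
def composites(small_scene):
    optical = percentile_range_composite(
        mask_clouds(small_scene.optical_series, 0.5), CompositeSpec())
    radar = percentile_range_composite(small_scene.radar_series, CompositeSpec())
    return optical, radar


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
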