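import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from swardmap.rasters import GridSpec, RasterStack
from swardmap.synthetic import SceneConfig, SceneLayout, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_grid():
    return GridSpec(origin_x=0.0, origin_y=8.0, pixel_size=1.0, n_rows=8, n_cols=8)


def small_scene_config(seed: int = 7, **overrides) -> SceneConfig:
    kwargs = dict(
        pixel_size_m=0.02,
        layout=SceneLayout(plot_size_m=1.28, n_subplots=6),
        seed=seed,
    )
    kwargs.update(overrides)
    return SceneConfig(**kwargs)


@pytest.fixture(scope="session")
def small_scene():
    """64-px plots, 8 plots: quick but fully structured scene."""
    return generate_scene(small_scene_config(), "ms")


@pytest.fixture
def rgb_stack(rng):
    grid = GridSpec(0.0, 6.0, 1.0, 6, 6)
    stack = RasterStack(grid, value_domain="dn_0_255")
    for name in ("red", "green", "blue"):
        stack.add_band(name, rng.uniform(0, 255, grid.shape))
    return stack
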