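import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lrbend as lb

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def small_grid():
    """2x2 grid of unit cells (9 vertices), the smallest valid tissue."""
    return lb.build_lr_grid(2, 2, 1.0, 1.0)


@pytest.fixture
def default_grid():
    """The frozen default geometry with zones assigned."""
    geo = lb.GeometryConfig()
    t = lb.build_lr_grid(geo.n_cols, geo.n_rows, geo.cell_width, geo.cell_height)
    return lb.assign_zones(t, geo.tip_zone_length)


@pytest.fixture
def perturbed_small_grid(small_grid):
    """2x2 grid with a reproducible perturbation of the free vertices."""
    rng = np.random.default_rng(7)
    small_grid.positions += np.where(
        small_grid.fixed_x[:, None], 0.0, rng.normal(0, 0.05, (9, 2)))
    return small_grid
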