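import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def small_grid():
    from exotran.geometry import GridSpec, build_grid

    return build_grid(GridSpec(nx=16, ny=16, dx=1e-3, dy=1e-3))


@pytest.fixture
def all_fluid(small_grid):
    from exotran.benchmark import all_fluid_mask

    return all_fluid_mask(small_grid)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
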