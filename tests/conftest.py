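import numpy as np
import pytest
from hypothesis import settings

from fcs3c.models import SpeciesParams, default_lag_grid, eval_single_2d

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def lag_grid():
    """Default fit-range grid: log-spaced 1e-2..1e3 ms, 200 points."""
    return default_lag_grid(1e-2, 1e3, 200)


@pytest.fixture
def clean_2d_curve(lag_grid):
    """Noiseless single-species 2D curve with N=5, tau_d=4 ms."""
    return eval_single_2d(lag_grid, SpeciesParams(n=5.0, tau_d=4.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)
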