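import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from proximo.rda import ModelParams, SimGrid
from proximo.synthetic import GroundTruth, make_profile_series


@pytest.fixture(scope="session")
def small_grid():
    """Desk-scale solver grid shared by the heavier tests."""
    return SimGrid(n0=100)


@pytest.fixture(scope="session")
def control_like_params():
    """Parameters in the neighbourhood of the control-condition estimates."""
    return ModelParams(r=0.08, D=1500.0, a=0.092, vp=12.0, L0=1000.0)


@pytest.fixture(scope="session")
def noisy_series(control_like_params, small_grid):
    """Seeded noisy synthetic series (additive-Normal observation model)."""
    gt = GroundTruth(control_like_params, noise_sigma=0.005, seed=11,
                     clip_noise=False)
    return make_profile_series(gt, small_grid, noise_on_ic=False)
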