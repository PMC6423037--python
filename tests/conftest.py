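import numpy as np
import pandas as pd
import pytest

from rbstscreen.design import StudyDesign, build_dose_schedule
from rbstscreen.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_design():
    return StudyDesign()


@pytest.fixture(scope="session")
def default_schedule(default_design):
    return build_dose_schedule(default_design)


#: reduced sampling grid: keeps the dose-cycle structure (dense first two
#: cycles, gap, follow-up) at ~1/3 the wells for fast curve-level tests
SMALL_SAMPLING_DAYS = (-18, -4, 1, 3, 7, 9, 14, 16, 21, 23, 28, 42, 56,
                       70, 84, 98, 126, 168, 196, 219)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(sampling_days=SMALL_SAMPLING_DAYS)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def logistic_curve(x0, efficiency, n_cycles=40, plateau=3000.0,
                   baseline=100.0, noise_sd=1.0, rng=None):
    """Ground-truth amplification curve generator used as a test oracle."""
    c = np.arange(1, n_cycles + 1)
    ec = efficiency ** c.astype(float)
    x = x0 * ec / (1.0 + x0 * (ec - 1.0) / plateau)
    f = baseline + x
    if noise_sd and rng is not None:
        f = f + rng.normal(0.0, noise_sd, n_cycles)
    return f


@pytest.fixture(scope="session")
def sim_config(small_design):
    return SimulationConfig(seed=0, design=small_design)
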