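import warnings

import numpy as np
import pytest

from shoalresp.respirometry import ChamberGeometry, PhaseSchedule
from shoalresp.simulate import SimConfig

# statsmodels emits convergence chatter on tiny fixtures; keep test output clean
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=20240817)


@pytest.fixture(scope="session")
def schedule() -> PhaseSchedule:
    return PhaseSchedule()


@pytest.fixture(scope="session")
def geometry() -> ChamberGeometry:
    return ChamberGeometry(fish_mass_g=1.29)


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """One small but complete simulated study, shared across tests."""
    from shoalresp.simulate import config_with, simulate_cohort

    cfg = config_with(
        default_config,
        n_fish_per_treatment=4,
        n_shoals_per_treatment=4,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_results(small_cohort):
    from shoalresp.pipeline import process_cohort

    return process_cohort(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(991)
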