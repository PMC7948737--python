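import numpy as np
import pytest

from glycokinetics.data import NoiseSpec
from glycokinetics.rate_laws import KineticParameters
from glycokinetics.synthetic_data import (
    DONOR_LEVELS_UM,
    ACCEPTOR_LEVELS_UM,
    REPORTED_PARAMS,
    simulate_velocity_dataset,
)


@pytest.fixture(scope="session")
def reported_params() -> KineticParameters:
    """The study's reported best-fit constants, used as generating truth."""
    return REPORTED_PARAMS


@pytest.fixture(scope="session")
def grid_levels() -> tuple[tuple[float, ...], tuple[float, ...]]:
    return DONOR_LEVELS_UM, ACCEPTOR_LEVELS_UM


@pytest.fixture(scope="session")
def exact_dataset(reported_params):
    """Noiseless velocities on the printed 5x5 grid, one observation per cell."""
    return simulate_velocity_dataset(reported_params, replicates=1, noise=NoiseSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
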