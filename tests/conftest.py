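import numpy as np
import pytest

from micellekin import ModelParameters, SimulationSetup, simulate


@pytest.fixture(scope="session")
def desk_params() -> ModelParameters:
    """Default rates at the reduced ladder truncation used for scans."""
    return ModelParameters(I_max=300, N_max=600)


@pytest.fixture(scope="session")
def default_trajectory(desk_params):
    """One unseeded reference run shared by the trajectory-level tests."""
    setup = SimulationSetup(c0=1.0, t_end=100.0, n_points=500)
    return simulate(setup, desk_params, keep_snapshots=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1729)
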