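import numpy as np
import pytest

from radstar.phantom import (
    CoilModel,
    Ellipse,
    PhantomSpec,
    Tissue,
    simulate_coils,
)
from radstar.trajectory import EchoTrain, build_trajectory


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def echo_train_35():
    """The 35-echo FLASH train (TE1 2.37 ms, spacing 1.88 ms)."""
    return EchoTrain(te_first=2.37, delta_te=1.88, n_echoes=35)


@pytest.fixture(scope="session")
def small_traj():
    """Small trajectory: 5 shots x 3 echoes on a 32-sample spoke."""
    return build_trajectory(n_shots=5, n_echoes=3, samples_per_spoke=32)


@pytest.fixture(scope="session")
def single_tube_phantom():
    """One off-centre tube in a water background on a 64 mm FOV."""
    return PhantomSpec(
        regions=[
            (Ellipse((0.0, 0.0), (55.0, 55.0)), Tissue(1.0, 0.0, 20.0, 0.0)),
            (Ellipse((10.0, -8.0), (11.0, 11.0)), Tissue(1.0, 30.0, 25.0, 20.0)),
        ],
        fov_mm=128.0,
        base_resolution=48,
    )


@pytest.fixture(scope="session")
def eight_coils():
    return simulate_coils(CoilModel(n_coils=8, seed=3), 96, 128.0)
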