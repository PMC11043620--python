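import numpy as np
import pytest

from idpflow.synthetic_data import (GuinierPorodTruth, make_guinier_porod_curve,
                                    make_ideal_helix)
from idpflow.trajectory_analysis import Trajectory


@pytest.fixture(scope="session")
def helix18():
    return make_ideal_helix(18)


@pytest.fixture(scope="session")
def helix89():
    return make_ideal_helix(89)


@pytest.fixture(scope="session")
def helix89_traj(helix89):
    return Trajectory(helix89.topology, helix89.coords[None])


@pytest.fixture(scope="session")
def gp_fixture_curve():
    """The canonical noisy round-trip fixture: R_G=30 Å, d=2, 1% noise."""
    return make_guinier_porod_curve(
        GuinierPorodTruth(R_G=30.0, d=2.0, noise_frac=0.01, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
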