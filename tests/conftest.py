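import warnings

import numpy as np
import pytest

from fibrilsurf import dynamics, lattice
from fibrilsurf.config import get_preset


@pytest.fixture(scope="session")
def reduced_model():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lattice.build_model("reduced")


@pytest.fixture(scope="session")
def schematic_model():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lattice.build_model("schematic")


@pytest.fixture(scope="session")
def calibrated_schedule_42(reduced_model):
    return dynamics.calibrated_schedule(reduced_model, seed=42)


@pytest.fixture(scope="session")
def calibrated_traj(reduced_model, calibrated_schedule_42):
    return dynamics.generate_trajectory(reduced_model, calibrated_schedule_42)


@pytest.fixture(scope="session")
def reduced_surface_profile(reduced_model):
    from fibrilsurf import sasa

    return sasa.residue_profile(reduced_model, probe=8.0,
                                restrict="surface_A")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def schematic_preset():
    return get_preset("schematic")


@pytest.fixture(scope="session")
def reduced_preset():
    return get_preset("reduced")
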