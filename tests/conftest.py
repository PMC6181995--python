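import numpy as np
import pytest
from hypothesis import settings

import cgtension as cg

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """Shipped default feedback-model parameters."""
    return cg.ModelParams.default()


@pytest.fixture(scope="session")
def stokes_zeta():
    """Drag of the default 500 nm bead in water, pN*s/nm."""
    return cg.zeta_from_stokes(500.0, 1.0)


@pytest.fixture(scope="session")
def long_bead_trajectory(stokes_zeta):
    """A 60 s, 20 kHz trajectory at k = 0.05 pN/nm (calibration fixture)."""
    return cg.gen_bead_trajectory(
        k=0.05, zeta=stokes_zeta, kBT=4.28, fs=20_000.0, duration=60.0, seed=7
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
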