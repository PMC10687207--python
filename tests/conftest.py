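import numpy as np
import pytest

from stellatesim.cable import (
    Morphology,
    PassiveParams,
    Section,
    SimConfig,
    build_cell,
)
from stellatesim import models


@pytest.fixture(scope="session")
def soma_morphology():
    return Morphology((Section(1, None, "soma", 20.0, 20.0),))


@pytest.fixture(scope="session")
def passive_cell(soma_morphology):
    """Single passive compartment: R = Rm/A, tau = Rm*Cm = 50 ms."""
    return build_cell(soma_morphology, PassiveParams())


@pytest.fixture(scope="session")
def fast_cfg():
    return SimConfig(dt=0.05, v_init=-70.0, settle_time=200.0)


@pytest.fixture(scope="session")
def ventral_cell():
    return models.ventral_cell()


@pytest.fixture(scope="session")
def rn_table_sim():
    """The four-arm R_N table from full 5-s step simulations (shared)."""
    return models.rn_table(dt=0.05)


@pytest.fixture(scope="session")
def t_kinetics():
    """Full voltage-clamp round trip on the T-current preparation (shared)."""
    return models.measure_t_kinetics(dt=0.05)
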