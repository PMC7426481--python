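import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from mcsgd import (
    AbsorptionField,
    LayeredSlab,
    QpatOracle,
    QpatProblem,
    UmotOracle,
    UmotProblem,
    make_grid,
    synthesize_observed,
)


@pytest.fixture(scope="session")
def grid5():
    return make_grid(5, 0.1)


@pytest.fixture(scope="session")
def slab5(grid5):
    """Small diffusive slab: 5 layers, 0.5 cm, mu_s=40/cm, g=0.9."""
    return LayeredSlab.uniform(grid5, 40.0, 0.9)


@pytest.fixture(scope="session")
def mu_true5(grid5):
    return AbsorptionField(grid5, np.array([0.1, 0.3, 0.5, 0.2, 0.4]))


@pytest.fixture(scope="session")
def qpat_oracle5(slab5, mu_true5):
    """QPAT oracle on the small slab with observed data from 2e6 packets."""
    h_obs = synthesize_observed("qpat", slab5, mu_true5, 2_000_000, seed=11)
    return QpatOracle(QpatProblem(slab5, h_obs))


@pytest.fixture(scope="session")
def umot_oracle5(slab5, mu_true5):
    b_obs = synthesize_observed("umot", slab5, mu_true5, 2_000_000, seed=12)
    return UmotOracle(UmotProblem(slab5, b_obs))
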