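import numpy as np
import pytest

from riboalloc.params import (
    AllocationTriple,
    SimpleKinetics,
    default_flux_parity_kinetics,
    default_simple_kinetics,
)


@pytest.fixture(scope="session")
def simple_kinetics_ref():
    """The worked simple-model parameter point (gamma=10, nu=4, Km=0.01)."""
    return SimpleKinetics(gamma_max=10.0, nu_max=4.0, Km_cpc=0.01)


@pytest.fixture(scope="session")
def allocation_ref():
    """Allocation (phi_Rb=0.2, phi_O=0.3) whose analytic growth rate is 20/11."""
    return AllocationTriple(phi_Rb=0.2, phi_Mb=0.5, phi_O=0.3)


@pytest.fixture(scope="session")
def fp_kinetics():
    return default_flux_parity_kinetics()


@pytest.fixture(scope="session")
def ecoli_kinetics():
    return default_simple_kinetics()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
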