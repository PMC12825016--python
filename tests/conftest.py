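import numpy as np
import pytest

from nanopbpk import DoseSpec, load_kinetics, load_physiology


@pytest.fixture(scope="session")
def mouse_phys():
    return load_physiology("mouse")


@pytest.fixture(scope="session")
def human_phys():
    return load_physiology("human")


@pytest.fixture(scope="session")
def meso_kin():
    return load_kinetics("Meso")


@pytest.fixture(scope="session")
def mouse_dose():
    """Standard murine regimen: 20 mg/kg into a 0.02 kg mouse = 400 µg."""
    return DoseSpec.from_per_bw(20.0, 0.02)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
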