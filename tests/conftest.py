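import numpy as np
import pytest

from photokin import ExperimentGeometry, IrradiationSource, QuantumYields
from photokin.synthetic import (
    AZOBENZENE_LIKE,
    default_experiment,
    make_toy_switch,
)


@pytest.fixture(scope="session")
def toy_system():
    return make_toy_switch(AZOBENZENE_LIKE)


@pytest.fixture(scope="session")
def geometry():
    return ExperimentGeometry(volume_L=3.0e-3)


@pytest.fixture(scope="session")
def mono_340():
    """~1 mW of 340 nm light: photon flux ~1.7e15 photons/s."""
    return IrradiationSource(photon_flux=1.7116e15, wavelength_nm=340.0)


@pytest.fixture(scope="session")
def true_phis():
    return QuantumYields(0.16, 0.38)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Reference-condition synthetic run without noise (1 h, 30 s sampling)."""
    return default_experiment(noise_sd=0.0)
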