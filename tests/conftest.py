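import numpy as np
import pytest

from cisim import cochlea, excitation, sound_coding as sc
from cisim.anf import NeuronParams


@pytest.fixture(scope="session")
def tiny_interface():
    """Small but fully featured interface (fast to excite)."""
    cfg = cochlea.CochleaConfig(n_fibers=121)
    return cochlea.build_geometry(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_interface):
    return excitation.ExcitationModel(tiny_interface)


@pytest.fixture(scope="session")
def degenerated_interface(tiny_interface):
    return cochlea.apply_degeneration(tiny_interface, 10, 3, seed=7)


@pytest.fixture(scope="session")
def flat_map():
    """A plausible fitted map for coder tests (MCL 100, T 10)."""
    return sc.FittingMap(mcl_cu=np.full(sc.N_CHANNELS, 100.0))


@pytest.fixture(scope="session")
def quiet_params():
    """Neuron parameters with the noise switched off (deterministic)."""
    return NeuronParams(noise_sd_a=0.0)
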