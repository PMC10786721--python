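import numpy as np
import pytest

from cellsqueeze import (CellModelParams, SimulationConfig, build_device,
                         device_preset, make_cell_mesh, to_lattice)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_units(default_config):
    return to_lattice(default_config)


@pytest.fixture(scope="session")
def device2(default_units):
    return build_device(device_preset("device2"), default_units)


@pytest.fixture(scope="session")
def cell16():
    """Standard-resolution 16 um cell mesh (642 vertices)."""
    return make_cell_mesh(16.0)


@pytest.fixture(scope="session")
def table2_params_16um():
    """Identified parameter set for the 16 um cell."""
    return CellModelParams(K_l=23203.0, K_b=45526.0, K_a=19816.0,
                           K_v=93182.0, VR=19.9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
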