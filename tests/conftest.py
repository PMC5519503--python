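import numpy as np
import pytest

import phasegraph as pg


@pytest.fixture(scope="session")
def hwp():
    """Default-order Hilbert wavelet pair, shared across tests."""
    return pg.design_hwp_filters(3)


@pytest.fixture(scope="session")
def small_dataset():
    """A small coupled-oscillator dataset: 16 regions, 256 volumes, 2 hubs."""
    coupling = pg.make_planted_hub_network(16, hub_ids=(0, 1), seed=7)
    spec = pg.SimulationSpec(n_regions=16, n_timepoints=256,
                             coupling_matrix=coupling, hub_ids=(0, 1), seed=7)
    ts = pg.simulate_coupled_bold(spec)
    rcps, suv = pg.synth_pet_vectors(coupling.sum(axis=1), seed=8)
    return coupling, ts, rcps, suv


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
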