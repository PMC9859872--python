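import numpy as np
import pytest

from lfaquant import SimulationConfig, default_layout, simulate_batch
from lfaquant.calibrate import fit_4pl
from lfaquant.simulate import simulate_normalized_signals


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def exact_config():
    """Idealized render: no noise, no gradient, hard-edged spots."""
    return SimulationConfig(noise_sd=0.0, gradient_amplitude=0.0,
                            edge_sigma=0.0, n_strips=1)


@pytest.fixture(scope="session")
def exact_records(exact_config, layout):
    return simulate_batch(exact_config, layout)


@pytest.fixture(scope="session")
def noisy_fit():
    """A fixed 4PL fit on signal-level replicates (sigma = 0.03)."""
    cfg = SimulationConfig(seed=42)
    conc, y = simulate_normalized_signals(cfg, 0.03, n_replicates=4,
                                          rng=np.random.default_rng(42))
    return fit_4pl(conc, y)
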