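import numpy as np
import pytest

from idrscape.synthetic import SimConfig, simulate_dataset, simulate_protein


@pytest.fixture(scope="session")
def driver_protein():
    """One driver-like synthetic protein at default generator parameters."""
    cfg = SimConfig(seed=11)
    return simulate_protein(cfg, np.random.default_rng(11), "drv0001",
                            group="driver", motif_multiplier=2.0)


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-group dataset (2 proteins/group) at default parameters."""
    cfg = SimConfig(seed=7, n_proteins=2)
    return simulate_dataset(cfg)
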