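import numpy as np
import pytest

from megblup import genotypes as gt
from megblup import simulate as sim


@pytest.fixture(scope="session")
def small_trial():
    """A fast truth-known trial: 100 lines x 1000 markers x 4 env x 2 reps."""
    config = sim.get_preset("small-test", seed=42)
    g, table, truth = sim.simulate_trial(config)
    return config, g, table, truth


@pytest.fixture(scope="session")
def small_grm(small_trial):
    _, g, _, _ = small_trial
    return gt.compute_grm(g)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
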