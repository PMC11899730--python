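import numpy as np
import pytest

from nlrsurvey.synthetic_data import SimulationConfig, simulate_survey


@pytest.fixture(scope="session")
def small_survey():
    """A 40-gene noise-free synthetic survey shared across read-only tests."""
    cfg = SimulationConfig(n_genes=40, motif_divergence=0.0, seed=11)
    return simulate_survey(cfg)


@pytest.fixture(scope="session")
def default_survey():
    """A survey at the default conditions (252 genes, 10% motif divergence)."""
    cfg = SimulationConfig(seed=42)
    return simulate_survey(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
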