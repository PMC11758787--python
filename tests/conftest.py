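import numpy as np
import pytest

from seq2msa import ModelConfig, SimulationConfig, fit, pairwise_config, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_records():
    """A handful of 5-sequence records with plenty of indels."""
    cfg = SimulationConfig(n_sequences=5, n_records=30, root_length_range=(15, 25),
                           RI_range=(0.02, 0.05), RD_range=(0.02, 0.05), seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def pairwise_records():
    return simulate_dataset(pairwise_config(n_records=60, seed=5))


@pytest.fixture(scope="session")
def tiny_model():
    """A quickly trained pairwise aligner for plumbing tests (not accuracy)."""
    recs = simulate_dataset(pairwise_config(n_records=300, root_length_range=(8, 12), seed=31))
    cfg = ModelConfig(epochs=10, seed=1)
    return fit([(r.source, r.target) for r in recs], cfg)
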