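import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")

from lombardkit.synthetic import CONDITIONS, GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small rendered synthetic dataset shared across tests."""
    cfg = GeneratorConfig(n_participants=5, n_items=6, seed=202)
    sessions, truth = generate_dataset(cfg)
    return cfg, sessions, truth


@pytest.fixture(scope="session")
def conditions():
    return list(CONDITIONS)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
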