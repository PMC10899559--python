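import numpy as np
import pytest

from longict.model import ModelConfig, TwoLevelAttentionModel
from longict.synthetic import PhantomConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """10 phantom patients with retained volumes, shared across tests."""
    cfg = PhantomConfig(n_patients=10, seed=7, patch_size=32)
    records, truths = simulate_cohort(cfg, keep_volumes=True)
    return cfg, records, truths


@pytest.fixture(scope="session")
def small_model():
    return TwoLevelAttentionModel(
        ModelConfig(d=32, n_heads=4, n_layers=2, patch_size=32, cnn_width=4,
                    seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
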