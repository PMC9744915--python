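import numpy as np
import pytest

from lesiontrace import SimConfig, generate_domain_pair
from lesiontrace.embedding_net import NetworkConfig
from lesiontrace.trainer import TracerModel, TrainConfig


@pytest.fixture(scope="session")
def small_sim():
    """A quick, well-separated source/target pair for unit tests."""
    cfg = SimConfig(
        n_genes=200,
        source_classes=4,
        common_classes=3,
        cells_per_class_source=30,
        cells_per_class_target=15,
        class_signature_size=12,
        shift_magnitude=1.0,
        noise_sd=0.5,
        wbc_classes=2,
        seed=42,
    )
    return cfg, generate_domain_pair(cfg)


@pytest.fixture(scope="session")
def small_net_config():
    return NetworkConfig(
        n_genes=200, n_classes=4, hidden_widths_extractor=[128, 64, 64], embed_dim=32
    )


@pytest.fixture(scope="session")
def small_fit(small_sim, small_net_config):
    """One short fitted model shared by trainer/downstream tests."""
    cfg, (src, tgt) = small_sim
    model = TracerModel(
        src, tgt, net_config=small_net_config,
        # fixture-scale problems separate quickly at a larger step size
        train_config=TrainConfig(epochs=80, initial_lr=1e-3, seed=7),
    )
    return model, model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
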