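import numpy as np
import pytest

from avehybrid import ModelConfig, TrainConfig, generate_synthetic


@pytest.fixture(scope="session")
def easy_dataset():
    """Well-separated planted-outlier benchmark (the easy recovery suite)."""
    return generate_synthetic(
        n=2000, d=10, contamination=0.05, mechanism="shifted_cluster",
        separation=8.0, n_clusters=1, seed=0,
    )


@pytest.fixture(scope="session")
def moderate_dataset():
    """Moderate-separation suite where label noise has measurable effect."""
    return generate_synthetic(
        n=2000, d=10, contamination=0.05, mechanism="shifted_cluster",
        separation=4.0, n_clusters=1, seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Small fixture for fast pipeline tests."""
    return generate_synthetic(
        n=400, d=6, contamination=0.05, mechanism="shifted_cluster",
        separation=6.0, n_clusters=1, seed=1,
    )


@pytest.fixture
def small_config(small_dataset):
    return ModelConfig(input_dim=small_dataset.d, hidden_dims=(16, 8), latent_dim=2, seed=0)


@pytest.fixture
def fast_train():
    return TrainConfig(epochs=15, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
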