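import numpy as np
import pytest

from unitednet.data import ModalityMatrix
from unitednet.network import ModelConfig
from unitednet.simulate import GeneratorSpec, simulate_multimodal
from unitednet.training import train


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_dataset():
    """Tiny labeled two-modality dataset with clear group structure."""
    return simulate_multimodal(
        GeneratorSpec(
            n_cells=120,
            n_groups=3,
            n_modalities=2,
            n_features=(15, 12),
            separation=8.0,
            noise_sd=0.4,
            seed=11,
        )
    )


@pytest.fixture
def tiny_modality():
    return ModalityMatrix(
        name="m",
        values=np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 6.0]]),
        feature_names=["f1", "f2", "f3"],
    )


@pytest.fixture(scope="session")
def trained_small_model():
    """A briefly trained model on small, well-separated data (shared
    across tests that only need a plausibly trained network)."""
    ds = simulate_multimodal(
        GeneratorSpec(
            n_cells=150,
            n_groups=3,
            n_modalities=2,
            n_features=(15, 12),
            separation=8.0,
            noise_sd=0.4,
            seed=21,
        )
    )
    cfg = ModelConfig(n_groups=3, epochs=12, batch_size=75, seed=1)
    return train(ds, cfg), ds
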