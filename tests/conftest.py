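import numpy as np
import pytest

from mganet.config import ModelConfig
from mganet.phantoms import generate_sample
from mganet.training import PhantomArrayDataset


def make_samples(n: int, size: int, seed: int, decoration: str = "none"):
    """Alternating benign/malignant phantoms from seeded child streams."""
    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2**31 - 1, n)
    return [
        generate_sample("benign" if i % 2 == 0 else "malignant", size,
                        int(child[i]), decoration)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(width_multiplier=1 / 8, input_size=64)


@pytest.fixture(scope="session")
def phantom_batch():
    """Twelve 64-px phantoms shared across read-only tests."""
    return make_samples(12, 64, seed=2024)


@pytest.fixture(scope="session")
def tiny_datasets():
    """64 train / 32 val phantoms at 64 px, the desk-scale study size."""
    samples = make_samples(96, 64, seed=123)
    return (PhantomArrayDataset.from_samples(samples[:64]),
            PhantomArrayDataset.from_samples(samples[64:]))
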