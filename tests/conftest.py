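import numpy as np
import pytest

from carunet.models import ModelConfig
from carunet.synthetic import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def phantoms32():
    """Ten small phantoms for fast end-to-end runs."""
    return generate_dataset(10, PhantomConfig(image_size=32, seed=11))


@pytest.fixture(scope="session")
def phantoms64():
    """Eight mid-size phantoms used by the learning-sanity checks."""
    return generate_dataset(8, PhantomConfig(image_size=64, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_config(arch: str, input_size: int = 32, activation: str = "leaky_relu"):
    """A very small but structurally complete model configuration."""
    return ModelConfig(arch, (4, 6, 8, 10, 12), reduction_ratio=4,
                       spatial_divisor=4, input_size=input_size,
                       activation=activation)
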