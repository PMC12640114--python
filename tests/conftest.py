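import numpy as np
import pytest

from plastinet.imagesets import LabeledImageSet, SyntheticSetSpec, generate_dataset
from plastinet.network import ArchConfig, ConvLayerSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast dataset for unit-level training tests."""
    return SyntheticSetSpec(
        n_classes=4, train_per_class=12, test_per_class=6,
        image_size=32, hue_sharing=2, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_sets(tiny_spec):
    return generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_arch():
    return ArchConfig(
        conv_layers=(ConvLayerSpec(4, 3, 1, True), ConvLayerSpec(8, 3, 1, True)),
        fc_layers=(16,),
        n_classes=4,
        input_size=24,
    )


@pytest.fixture(scope="session")
def random_image(rng):
    return rng.random((32, 32, 3))
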