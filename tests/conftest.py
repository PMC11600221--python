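import numpy as np
import pytest

import gafsense as gs


@pytest.fixture(scope="session")
def wine_dataset():
    """Default-condition wine layout: 7 classes x 10 replicates."""
    return gs.generate_task_dataset("wine", gs.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def wine_images(wine_dataset):
    images, labels, _ = gs.encode_dataset(wine_dataset, resolution=96)
    return images, labels


@pytest.fixture(scope="session")
def extractor():
    return gs.FeatureExtractor(gs.builtin_spec(96))


@pytest.fixture(scope="session")
def wine_fingerprints(wine_dataset, extractor):
    return gs.featurize_dataset(wine_dataset, extractor)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels):
    """Wrap a raw pixel array (H x W x 3 uint8) as a RenderedImage."""
    pixels = np.asarray(pixels, dtype=np.uint8)
    return gs.RenderedImage(pixels=pixels, resolution=pixels.shape[0])
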