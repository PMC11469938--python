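import numpy as np
import pytest

import fibroscore as fs
from fibroscore.labels import CLASS_ORDER


@pytest.fixture(scope="session")
def default_params():
    return fs.TextureParams()


@pytest.fixture(scope="session")
def noiseless_params():
    return fs.TextureParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_corpus():
    """12 tiles per class across all 10 classes, default texture, seed 5."""
    return fs.generate_labeled_dataset({c: 12 for c in CLASS_ORDER}, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_section(pixels, **kwargs):
    return fs.SectionImage(pixels=np.asarray(pixels, dtype=np.uint8), **kwargs)
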