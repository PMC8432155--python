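import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from polyqhcs import synthio


@pytest.fixture(scope="session")
def default_field():
    """One default 512x512 synthetic field plus ground truth."""
    spec = synthio.SynthImageSpec(seed=11)
    return synthio.make_field(spec)


@pytest.fixture(scope="session")
def clean_field():
    """Field with no touching pairs: segmentation should be exact."""
    spec = synthio.SynthImageSpec(seed=7, touching_pair_fraction=0.0)
    return synthio.make_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spot_images(n, shape=(16, 16), seed=0):
    """Mixed-range random integer images (small ranges force plateaus)."""
    rng = np.random.default_rng(seed)
    images = []
    for i in range(n):
        if i % 2 == 0:
            img = rng.integers(0, 12, size=shape)
        else:
            img = rng.integers(0, 3000, size=shape)
        images.append(img.astype(np.float64))
    return images
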