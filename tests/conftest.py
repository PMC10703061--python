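import numpy as np
import pytest

from rbscreen.synthetic import SyntheticImageSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image_spec():
    """A quick-to-render fundus spec used across image tests."""
    return SyntheticImageSpec(width=64, height=64, tumor_radius_range=(6, 10), seed=7)
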