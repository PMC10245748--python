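import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dendrite():
    """A 256x256 dendrite mask with a few wide lines (fast unit-test scene)."""
    from synapcount.simulate import generate_dendrites

    return generate_dendrites(n_segments=8, width_px=5, shape=(256, 256), seed=42)
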