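import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.4):
    """Random binary mask with occasional empty/full degenerate draws."""
    u = rng.random()
    if u < 0.05:
        return np.zeros(shape, dtype=np.uint8)
    if u < 0.10:
        return np.ones(shape, dtype=np.uint8)
    return (rng.random(shape) < p).astype(np.uint8)
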