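import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_qimage(rng):
    """Factory for random quaternion images of a given shape."""

    def make(m, n, pure=False):
        q = rng.normal(size=(m, n, 4))
        if pure:
            q[..., 0] = 0.0
        return q

    return make
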