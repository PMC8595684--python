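import numpy as np
import pytest


def gaussian_blob_field(rng, shape, n_blobs=20, noise=0.01):
    """Synthetic cell-like reference field: random Gaussian blobs."""
    img = np.zeros(shape)
    for _ in range(n_blobs):
        r = rng.uniform(8, shape[0] - 8)
        c = rng.uniform(8, shape[1] - 8)
        rad = rng.uniform(4, 8)
        amp = rng.uniform(0.5, 1.5)
        rr = np.arange(shape[0])[:, None] - r
        cc = np.arange(shape[1])[None, :] - c
        img += amp * np.exp(-(rr ** 2 + cc ** 2) / (2 * rad ** 2))
    return img + noise * rng.standard_normal(shape)


def disk_mask(shape, center, radius):
    rr = np.arange(shape[0])[:, None] - center[0]
    cc = np.arange(shape[1])[None, :] - center[1]
    return np.hypot(rr, cc) <= radius


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
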