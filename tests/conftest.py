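import numpy as np
import pytest

from socgrade import VoxelMask


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_mask_pair(rng):
    """Two random nonempty blobs on a shared small grid."""

    def _make(shape=(12, 12, 12), spacing=(1.0, 1.0, 3.0), p=0.3):
        while True:
            a = rng.random(shape) < p
            b = rng.random(shape) < p
            if a.any() and b.any():
                return (
                    VoxelMask(a, spacing=spacing),
                    VoxelMask(b, spacing=spacing),
                )

    return _make
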