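import numpy as np
import pytest

from contourqa import BinaryMask, MaskPair


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_mask(rng, shape=(12, 12), p=0.35) -> np.ndarray:
    """Random nonempty binary grid."""
    while True:
        g = (rng.random(shape) < p).astype(np.uint8)
        if g.any():
            return g


def random_pair(rng, shape=(12, 12)) -> MaskPair:
    return MaskPair(
        BinaryMask(random_mask(rng, shape)), BinaryMask(random_mask(rng, shape))
    )


@pytest.fixture
def shifted_block_pair() -> MaskPair:
    """2x2 truth block at the origin of a 4x3 grid, prediction shifted one column.

    TP=2, FP=2, FN=2, TN=6: dice 0.5, precision 0.5, sensitivity 0.5,
    accuracy 8/12.
    """
    t = np.zeros((4, 3), dtype=np.uint8)
    t[0:2, 0:2] = 1
    p = np.zeros((4, 3), dtype=np.uint8)
    p[0:2, 1:3] = 1
    return MaskPair(BinaryMask(t), BinaryMask(p), slice_id="shifted")
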