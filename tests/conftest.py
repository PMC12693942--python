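import numpy as np
import pytest

from aqa.skeleton import N_KEYPOINTS, KeypointSequence
from aqa.synthetic import generate_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n=8, fps=30.0, missing=0):
    """A valid random keypoint sequence; optionally mark keypoints missing."""
    coords = rng.normal(size=(n, N_KEYPOINTS, 3))
    for _ in range(missing):
        f = int(rng.integers(1, n))
        k = int(rng.integers(0, N_KEYPOINTS))
        coords[f, k] = np.nan
    return KeypointSequence(coords, fps)


@pytest.fixture
def small_template():
    return generate_template(64, 30.0, "reach", seed=1)
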