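import math

import numpy as np
import pytest

from clumm.synth import SyntheticDatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """3 motion classes x 60 frames at default noise conditions."""
    return generate_dataset(SyntheticDatasetConfig(frames_per_class=60, seed=7))


def ntxent_bruteforce(z1, z2, temperature):
    """Independent NT-Xent evaluation: explicit loops over every anchor.

    Enumerates all pairwise cosine similarities and softmax terms directly
    from the loss definition, with no vectorization shared with the
    implementation under test.
    """
    views = [np.asarray(v, dtype=float) for v in list(z1) + list(z2)]
    b = len(z1)
    n = 2 * b

    def cos(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0.0 or nv == 0.0:
            return 0.0
        return float(u @ v / (nu * nv))

    total = 0.0
    for i in range(n):
        pos = (i + b) % n
        numerator = math.exp(cos(views[i], views[pos]) / temperature)
        denominator = sum(
            math.exp(cos(views[i], views[k]) / temperature) for k in range(n) if k != i
        )
        total += -math.log(numerator / denominator)
    return total / n
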