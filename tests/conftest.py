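import numpy as np
import pytest

import dendril as dl


@pytest.fixture(scope="session")
def graph1():
    """Single default branch (1 λ) + junction, 0.01 X grid."""
    return dl.discretise(dl.build_star_tree(1), 0.01)


@pytest.fixture(scope="session")
def graph4():
    """Four default branches + junction, 0.01 X grid."""
    return dl.discretise(dl.build_star_tree(4), 0.01)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220923)


def random_tree(rng: np.random.Generator, n: int):
    """Random Hines-ordered tree: parent pointers, couplings, diagonal."""
    parent = np.array(
        [-1] + [int(rng.integers(0, k)) for k in range(1, n)], dtype=np.int64
    )
    g = np.concatenate(([0.0], rng.uniform(0.5, 5.0, n - 1)))
    leak = rng.uniform(0.1, 2.0, n)
    gsum = g.copy()
    np.add.at(gsum, parent[1:], g[1:])
    return parent, g, leak + gsum
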