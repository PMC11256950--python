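import random

import pytest

from rnatrees.core import RnaTree, structure_to_tree
from rnatrees.simulate import sample_uniform_structure


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240229)


def random_tree(n: int, theta: int, rng: random.Random) -> RnaTree:
    return structure_to_tree(sample_uniform_structure(n, theta, rng))


@pytest.fixture
def make_trees():
    """Factory: p independent uniform random trees of length n."""

    def factory(p: int, n: int, theta: int = 0, seed: int = 0):
        r = random.Random(seed)
        return [random_tree(n, theta, r) for _ in range(p)]

    return factory
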