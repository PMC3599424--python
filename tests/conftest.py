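import pytest

from mct.datasets import example_profile
from mct.simulate import make_random_profile


@pytest.fixture(scope="session")
def profile5():
    """The five-tree, seven-leaf worked-example profile."""
    return example_profile()


@pytest.fixture
def random_tree():
    """Factory for seeded uniform random resolved trees."""

    def make(n=8, seed=0):
        return make_random_profile(1, n, seed)[0]

    return make
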