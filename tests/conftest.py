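import pytest

from scgclust import RankMatrix
from scgclust.datasets import random_point_ranks, random_rank_matrix, seven_object_ranks


@pytest.fixture
def seven_rm() -> RankMatrix:
    return seven_object_ranks()


@pytest.fixture
def make_rank_matrix():
    """Callable (rng, n) -> arbitrary valid rank matrix."""
    return lambda rng, n: random_rank_matrix(rng, n)


@pytest.fixture
def make_point_ranks():
    """Callable (rng, n) -> rank matrix of a random planar point set."""
    return lambda rng, n: random_point_ranks(rng, n)
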