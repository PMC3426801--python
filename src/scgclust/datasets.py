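"""Small built-in and randomly generated datasets for documentation,
benchmarking and oracle-based testing."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .ranking import ObjectSet, RankMatrix, ScoreMatrix, build_rank_matrix

__all__ = [
    "seven_object_ranks",
    "seven_object_distances",
    "random_rank_matrix",
    "random_point_ranks",
    "SEVEN_OBJECT_RMATRIX",
]

# A seven-object rank matrix with a rich, fully known cluster structure:
# clusters {3,4}, {6,7}, {2,3,4}, {5,6,7}, {1,2,3,4}; independent clusters
# {1,2,3,4} and {5,6,7}.  Used as the canonical walk-through of all three
# algorithms.
SEVEN_OBJECT_RMATRIX = np.array(
    [
        [1, 4, 3, 2, 7, 5, 6],
        [4, 1, 2, 3, 5, 7, 6],
        [4, 3, 1, 2, 7, 5, 6],
        [4, 3, 2, 1, 6, 7, 5],
        [4, 7, 5, 6, 1, 2, 3],
        [5, 4, 6, 7, 3, 1, 2],
        [7, 5, 4, 6, 3, 2, 1],
    ],
    dtype=np.int64,
)


def seven_object_ranks() -> RankMatrix:
    """The seven-object example rank matrix (labels "1".."7")."""
    return RankMatrix(SEVEN_OBJECT_RMATRIX.copy(), objects=ObjectSet.numbered(7))


def seven_object_distances() -> ScoreMatrix:
    """A symmetric distance matrix whose rank transform reproduces the
    cluster structure of :func:`seven_object_ranks`.

    The asymmetric ranks themselves cannot all be realised by one symmetric
    metric; this synthetic surrogate (pairwise distance = a symmetrization of
    the ranks) yields the same SCG forest and is convenient for exercising
    file I/O and the command line.
    """
    r = SEVEN_OBJECT_RMATRIX.astype(float)
    d = np.maximum(r, r.T)  # max-symmetrized ranks reproduce the exact forest
    np.fill_diagonal(d, 0.0)
    return ScoreMatrix(d, orientation="distance", objects=ObjectSet.numbered(7))


def random_rank_matrix(rng: np.random.Generator | int | None, n: int) -> RankMatrix:
    """An arbitrary valid rank matrix: every row a uniform random permutation
    with the diagonal forced to 1.

    Such matrices need not be realisable by any metric; the cluster
    definition only requires the permutation structure, so they probe the
    algorithms on a strictly larger input space than point-derived ranks.
    """
    rng = np.random.default_rng(rng)
    rm = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        rng.shuffle(others)
        rm[i, i] = 1
        rm[i, others] = np.arange(2, n + 1)
    return RankMatrix(rm)


def random_point_ranks(
    rng: np.random.Generator | int | None, n: int, scale: float = 3.0
) -> RankMatrix:
    """Rank matrix of a random planar Gaussian point set (tie-free a.s.)."""
    rng = np.random.default_rng(rng)
    pts = rng.normal(size=(n, 2), scale=scale)
    return build_rank_matrix(ScoreMatrix(squareform(pdist(pts))))
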