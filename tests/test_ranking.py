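"""Rank-matrix construction: orderings, ties, sparse ingestion, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from scgclust import (
    ObjectSet,
    RankMatrix,
    ScoreMatrix,
    build_rank_matrix,
    densify_pair_scores,
)


def ranks_from_points(points):
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    return build_rank_matrix(ScoreMatrix(squareform(pdist(pts))))


class TestBuildRankMatrix:
    def test_single_object(self):
        rm = build_rank_matrix(ScoreMatrix(np.zeros((1, 1))))
        assert rm.rmatrix.tolist() == [[1]]
        assert rm.smatrix.tolist() == [[1]]

    def test_three_collinear_points(self):
        # points at 0, 1, 3: hand-sorted rows
        rm = ranks_from_points([0.0, 1.0, 3.0])
        assert [rm.rank(1, j) for j in (1, 2, 3)] == [1, 2, 3]
        assert [rm.rank(2, j) for j in (1, 2, 3)] == [2, 1, 3]
        assert [rm.rank(3, j) for j in (1, 2, 3)] == [3, 2, 1]

    @pytest.mark.parametrize("orientation", ["distance", "similarity"])
    def test_invariants_on_random_input(self, orientation):
        rng = np.random.default_rng(7)
        for n in (2, 5, 9):
            values = rng.normal(size=(n, n))  # asymmetric, accepted as-is
            rm = build_rank_matrix(ScoreMatrix(values, orientation=orientation))
            rm.validate()  # permutation rows, diagonal 1, smatrix inverse
            # explicit inverse-permutation identity per row
            for i in range(1, n + 1):
                for k in range(1, n + 1):
                    assert rm.rank(i, rm.row_order(i)[k - 1]) == k

    def test_similarity_ranks_descend(self):
        values = np.array([[9.0, 5.0, 2.0], [5.0, 9.0, 7.0], [2.0, 7.0, 9.0]])
        rm = build_rank_matrix(ScoreMatrix(values, orientation="similarity"))
        assert rm.rank(1, 2) == 2 and rm.rank(1, 3) == 3
        assert rm.rank(3, 2) == 2 and rm.rank(3, 1) == 3

    def test_self_rank_one_even_under_ties(self):
        rm = build_rank_matrix(ScoreMatrix(np.zeros((4, 4))))
        assert np.all(np.diagonal(rm.rmatrix) == 1)

    def test_ties_broken_by_ascending_id(self):
        # object 1 is equidistant from 2 and 3: 2 wins by id
        values = np.array([[0.0, 5.0, 5.0], [5.0, 0.0, 1.0], [5.0, 1.0, 0.0]])
        rm = build_rank_matrix(ScoreMatrix(values))
        assert rm.rank(1, 2) == 2 and rm.rank(1, 3) == 3

    def test_tie_rule_irrelevant_without_ties(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        sm = ScoreMatrix(squareform(pdist(pts)))
        assert np.array_equal(
            build_rank_matrix(sm, tie_rule="id").rmatrix, build_rank_matrix(sm).rmatrix
        )

    def test_errors(self):
        with pytest.raises(ValueError, match="square"):
            ScoreMatrix(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="non-finite"):
            values = np.zeros((3, 3))
            values[0, 1] = np.nan
            build_rank_matrix(ScoreMatrix(values))
        with pytest.raises(ValueError, match="tie_rule"):
            build_rank_matrix(ScoreMatrix(np.zeros((2, 2))), tie_rule="random")

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 10),
        scale=st.floats(0.5, 20.0),
        power=st.floats(0.2, 3.0),
    )
    def test_monotone_transform_invariance(self, seed, n, scale, power):
        """Ranks depend only on the ordering of distances."""
        rng = np.random.default_rng(seed)
        d = squareform(pdist(rng.normal(size=(n, 2))))
        base = build_rank_matrix(ScoreMatrix(d))
        transformed = build_rank_matrix(ScoreMatrix(scale * d**power + 1.0))
        assert np.array_equal(base.rmatrix, transformed.rmatrix)


class TestRankMatrixValidation:
    def test_rejects_non_permutation_rows(self):
        with pytest.raises(ValueError, match="permutation"):
            RankMatrix(np.array([[1, 2], [2, 3]]))

    def test_rejects_bad_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            RankMatrix(np.array([[2, 1], [2, 1]]))


class TestDensifyPairScores:
    def test_empty_pairs_rank_by_tie_rule(self):
        sm = densify_pair_scores([], objects=ObjectSet(("a", "b", "c")))
        rm = build_rank_matrix(sm)
        # all off-diagonal scores missing: order fixed purely by ascending id
        assert rm.rmatrix.tolist() == [[1, 2, 3], [2, 1, 3], [2, 3, 1]]

    def test_single_similarity_pair(self):
        sm = densify_pair_scores([("a", "b", 5.0)], objects=ObjectSet(("a", "b", "c")))
        rm = build_rank_matrix(sm)
        assert rm.rank(1, 2) == 2  # b is rank 2 in row a
        assert rm.rank(1, 3) == 3  # c missing, hence worst
        assert rm.rank(2, 1) == 2  # mirrored direction

    @pytest.mark.parametrize("worst_policy", ["mask", "fill"])
    def test_symmetric_full_list_round_trips(self, worst_policy):
        rng = np.random.default_rng(3)
        n = 5
        sim = rng.uniform(1, 10, size=(n, n))
        sim = 0.5 * (sim + sim.T)
        labels = tuple("abcde")
        pairs = [
            (labels[i], labels[j], float(sim[i, j]))
            for i in range(n)
            for j in range(n)
            if i != j
        ]
        dense = densify_pair_scores(
            pairs, objects=ObjectSet(labels), worst_policy=worst_policy
        )
        direct = ScoreMatrix(sim, orientation="similarity", objects=ObjectSet(labels))
        assert np.array_equal(
            build_rank_matrix(dense).rmatrix, build_rank_matrix(direct).rmatrix
        )

    def test_asymmetric_directions_kept(self):
        sm = densify_pair_scores(
            [("a", "b", 5.0), ("b", "a", 2.0), ("a", "c", 3.0)],
            objects=ObjectSet(("a", "b", "c")),
        )
        assert sm.values[0, 1] == 5.0 and sm.values[1, 0] == 2.0

    def test_duplicate_pairs(self):
        with pytest.warns(UserWarning, match="duplicate"):
            sm = densify_pair_scores(
                [("a", "b", 5.0), ("a", "b", 3.0)], objects=ObjectSet(("a", "b"))
            )
        assert sm.values[0, 1] == 5.0  # the better (larger) similarity wins
        with pytest.raises(ValueError, match="conflicting"):
            densify_pair_scores(
                [("a", "b", 5.0), ("a", "b", 3.0)],
                objects=ObjectSet(("a", "b")),
                strict_duplicates=True,
            )

    def test_unknown_id(self):
        with pytest.raises(KeyError, match="unknown object label"):
            densify_pair_scores([("a", "z", 1.0)], objects=ObjectSet(("a", "b")))
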