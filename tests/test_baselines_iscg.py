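"""Linkage baselines against independent oracles, and iterative SCG."""

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from scgclust import (
    LinkageSpec,
    Partition,
    ScoreMatrix,
    build_rank_matrix,
    iscg,
    linkage_partition,
    scg_a3,
)


def dist_of(points):
    pts = np.asarray(points, dtype=float).reshape(len(points), -1)
    return squareform(pdist(pts))


class TestLinkageSpec:
    def test_requires_exactly_one_mode(self):
        with pytest.raises(ValueError):
            LinkageSpec("complete")
        with pytest.raises(ValueError):
            LinkageSpec("complete", cutoff=2.0, n_clusters=3)
        with pytest.raises(ValueError, match="method"):
            LinkageSpec("ward", cutoff=2.0)


class TestLinkagePartition:
    def test_pair_below_cutoff_merges(self):
        part = linkage_partition(dist_of([0.0, 1.0]), LinkageSpec("complete", cutoff=2.0))
        assert part.n_groups == 1

    def test_chaining_separates_single_from_complete(self):
        d = dist_of([0.0, 1.5, 3.0])
        sl = linkage_partition(d, LinkageSpec("single", cutoff=2.0))
        cl = linkage_partition(d, LinkageSpec("complete", cutoff=2.0))
        assert sl.n_groups == 1  # chains through the middle point
        assert cl == Partition([{1, 2}, {3}], n=3)

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        d = dist_of(rng.normal(size=(6, 2)))
        part = linkage_partition(d, LinkageSpec("average", n_clusters=6))
        assert part == Partition.singletons(6)

    def test_k_mode_returns_exactly_k(self):
        rng = np.random.default_rng(2)
        d = dist_of(rng.normal(size=(12, 2), scale=4))
        for k in (1, 3, 7, 12):
            part = linkage_partition(d, LinkageSpec("complete", n_clusters=k))
            assert part.n_groups == k

    def test_errors(self):
        with pytest.raises(ValueError, match="symmetric"):
            linkage_partition(np.array([[0.0, 1.0], [2.0, 0.0]]), LinkageSpec("single", cutoff=1.0))
        with pytest.raises(ValueError, match="exceeds"):
            linkage_partition(dist_of([0.0, 1.0]), LinkageSpec("single", n_clusters=3))
        with pytest.raises(ValueError, match="distances"):
            linkage_partition(
                ScoreMatrix(np.eye(2), orientation="similarity"),
                LinkageSpec("single", cutoff=1.0),
            )

    def test_single_linkage_cutoff_equals_threshold_graph_components(self):
        """SL cut at delta == connected components of the <=delta graph —
        an independent oracle, exercised also with negative distances."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 20
            d = dist_of(rng.normal(size=(n, 2), scale=2))
            d += rng.normal(scale=1.0, size=(n, n))
            d = 0.5 * (d + d.T)
            np.fill_diagonal(d, 0.0)
            delta = float(rng.uniform(0.5, 3.0))
            part = linkage_partition(d, LinkageSpec("single", cutoff=delta))
            adj = (d <= delta) & ~np.eye(n, dtype=bool)
            n_comp, comp = connected_components(adj, directed=False)
            assert part == Partition.from_codes(comp)
            assert part.n_groups == n_comp

    def test_complete_linkage_cutoff_bounds_cluster_diameter(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            d = dist_of(rng.normal(size=(15, 2), scale=3))
            delta = float(rng.uniform(1.0, 5.0))
            part = linkage_partition(d, LinkageSpec("complete", cutoff=delta))
            for g in part.non_singletons():
                idx = np.array(sorted(g)) - 1
                assert d[np.ix_(idx, idx)].max() <= delta


# 1-D configuration: two tight end pairs, one tight middle pair.  No cluster
# larger than a pair can form in a single pass (the interlopers push ranks
# past the candidate size), but after collapsing, the left pair and the
# middle pair are mutual rank-2 neighbours and merge in pass 2.
SIX_POINTS = [0.0, 0.1, 0.45, 0.55, 1.05, 1.15]


class TestIterativeSCG:
    def _scores(self):
        return ScoreMatrix(dist_of(SIX_POINTS))

    def test_first_pass_equals_plain_scg(self):
        scores = self._scores()
        run = iscg(scores, strategy="min", max_iter=1)
        plain = scg_a3(build_rank_matrix(scores))
        assert run.forest == plain.forest
        assert run.forest.cluster_family() == {
            frozenset({1, 2}),
            frozenset({3, 4}),
            frozenset({5, 6}),
        }

    def test_second_pass_merges_collapsed_groups(self):
        run = iscg(self._scores(), strategy="min", max_iter=10)
        assert run.n_iter == 2
        assert run.forest.cluster_family() == {
            frozenset({1, 2}),
            frozenset({3, 4}),
            frozenset({5, 6}),
            frozenset({1, 2, 3, 4}),
        }
        assert run.independent_clusters == Partition([{1, 2, 3, 4}, {5, 6}], n=6)

    def test_fixed_point_is_stable(self):
        run10 = iscg(self._scores(), strategy="min", max_iter=10)
        run3 = iscg(self._scores(), strategy="min", max_iter=3)
        assert run10.forest == run3.forest  # extra iterations change nothing

    @pytest.mark.parametrize("strategy", ["min", "avg", "max"])
    def test_membership_grows_monotonically(self, strategy):
        rng = np.random.default_rng(9)
        for _ in range(5):
            scores = ScoreMatrix(dist_of(rng.normal(size=(14, 2), scale=2)))
            run = iscg(scores, strategy=strategy, max_iter=6)
            for earlier, later in zip(run.iterations, run.iterations[1:]):
                for g in earlier.groups:
                    assert any(g <= h for h in later.groups)

    def test_min_strategy_never_finer_than_plain_scg(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            scores = ScoreMatrix(dist_of(rng.normal(size=(12, 2), scale=2)))
            plain = scg_a3(build_rank_matrix(scores)).independent_clusters
            final = iscg(scores, strategy="min", max_iter=6).independent_clusters
            for g in plain.groups:
                assert any(g <= h for h in final.groups)

    def test_avg_update_variants_and_errors(self):
        scores = self._scores()
        a = iscg(scores, strategy="avg", max_iter=5, avg_update="pairwise")
        b = iscg(scores, strategy="avg", max_iter=5, avg_update="group")
        a.forest.validate()
        b.forest.validate()
        with pytest.raises(ValueError, match="strategy"):
            iscg(scores, strategy="median")
        with pytest.raises(ValueError, match="max_iter"):
            iscg(scores, max_iter=0)
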