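"""The self-consistency cluster test and the three SCG algorithms.

A set ``S`` of ``k`` objects is a *cluster* when every ordered pair inside it
is mutually close in rank: ``rank(x, y) <= k`` for all ``x, y`` in ``S``
(clusters of size ``n`` are disallowed).  Because each row of the rank matrix
is a permutation, any cluster containing ``x`` is exactly the first ``k``
entries of ``x``'s sorted row — which makes the full cluster family laminar
and reduces every algorithm to testing row prefixes.

Three algorithms share this primitive and differ only in how they schedule
the prefix tests:

``scg_a1``
    exhaustive sweep over sizes 2..n; deterministic; finds the complete
    subcluster structure.
``scg_a2``
    per-object scan driven by *candidate indices* (the maximum pairwise rank
    inside a failed prefix is a lower bound on the size of any cluster
    extending it).  Fastest; guaranteed to find all independent clusters but
    not the internal structure, and sensitive to the examination order.
``scg_a3``
    global scheduling by minimum candidate index; deterministic and
    equivalent to ``scg_a1``, usually much faster.

``enumerate_all_clusters`` is the brute-force oracle used by the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .forest import ClusterForest, Partition
from .ranking import RankMatrix

__all__ = [
    "is_cluster",
    "candidate_index",
    "scg_a1",
    "scg_a2",
    "scg_a3",
    "enumerate_all_clusters",
    "SCGRun",
]


def _check_members(members: Iterable[int], n: int) -> np.ndarray:
    idx = np.fromiter((int(m) for m in members), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("member set must be non-empty")
    if idx.min() < 1 or idx.max() > n:
        raise ValueError("member id out of range")
    if np.unique(idx).size != idx.size:
        raise ValueError("duplicate member ids")
    return idx - 1


def is_cluster(members: Iterable[int], rm: RankMatrix) -> bool:
    """True iff *members* satisfies the SCG cluster test.

    Singletons are trivially clusters (``rank(x, x) = 1``); the full object
    set never is.  Cost is O(k^2) for k members.
    """
    idx = _check_members(members, rm.n)
    k = idx.size
    if k >= rm.n and rm.n > 1:
        return False
    if k == 1:
        return True
    return int(rm.rmatrix[np.ix_(idx, idx)].max()) <= k


def candidate_index(members: Iterable[int], rm: RankMatrix) -> int:
    """Maximum pairwise rank within *members*.

    Equals ``len(members)`` exactly when the set is a cluster (for sets
    smaller than n); when a prefix fails the cluster test, the candidate
    index is the minimum size of any cluster that could contain it.
    """
    idx = _check_members(members, rm.n)
    return int(rm.rmatrix[np.ix_(idx, idx)].max())


@dataclass
class SCGRun:
    """Result of one SCG algorithm run.

    ``examinations`` maps candidate-cluster size to the number of cluster
    tests charged at that size.  A1 charges every test it performs; A2/A3
    charge a test only when it succeeds or fails with an informative
    candidate index (< n) — a failure whose candidate index equals n simply
    retires the object.
    """

    forest: ClusterForest
    examinations: dict[int, int]
    algorithm: str
    complete: bool
    levels: tuple[int, ...] = ()  # A3: sequence of minimum indices processed

    @property
    def independent_clusters(self) -> Partition:
        return self.forest.independent_clusters()

    @property
    def n_examinations(self) -> int:
        return sum(self.examinations.values())


def _prefix_test(rmat: np.ndarray, row: np.ndarray, k: int, n: int) -> tuple[bool, int]:
    """Test the first *k* entries of a sorted row; return (is_cluster, candidate index)."""
    idx = row[:k] - 1
    ci = int(rmat[np.ix_(idx, idx)].max())
    return (ci <= k and k < n), ci


def scg_a1(rm: RankMatrix) -> SCGRun:
    """Direct SCG: test every size from 2 to n for every object.

    At each size f all objects are marked valid; objects absorbed into a
    cluster formed at this size are skipped for the rest of the sweep.  The
    complete subcluster structure is recovered.
    """
    n = rm.n
    forest = ClusterForest(n, labels=rm.labels)
    rmat, smat = rm.rmatrix, rm.smatrix
    examinations: dict[int, int] = {}
    for f in range(2, n + 1):
        iteration_valid = np.ones(n + 1, dtype=bool)
        for o in range(1, n + 1):
            if not iteration_valid[o]:
                continue
            examinations[f] = examinations.get(f, 0) + 1
            ok, _ = _prefix_test(rmat, smat[o - 1], f, n)
            if ok:
                members = smat[o - 1, :f]
                forest.merge(members, formed_by=f"a1:f={f}")
                iteration_valid[members] = False
    return SCGRun(forest=forest, examinations=examinations, algorithm="a1", complete=True)


def scg_a2(rm: RankMatrix, order: Sequence[int] | None = None) -> SCGRun:
    """SCG-fast: candidate-index driven scan, one object at a time.

    For each object (in *order*, default ascending id) the index starts at 2;
    a failed prefix jumps the index to its candidate index, a successful one
    records the cluster and increments the index.  The scan of a row stops
    when an already-invalid object enters the prefix, the candidate index
    reaches n, or the row is exhausted; the largest cluster found (possibly
    the singleton) is then marked permanently invalid.  All independent
    clusters are guaranteed; internal structure is incidental.
    """
    n = rm.n
    forest = ClusterForest(n, labels=rm.labels)
    rmat, smat = rm.rmatrix, rm.smatrix
    examinations: dict[int, int] = {}
    invalid = np.zeros(n + 1, dtype=bool)
    if order is None:
        order = range(1, n + 1)
    else:
        if sorted(int(o) for o in order) != list(range(1, n + 1)):
            raise ValueError("order must be a permutation of the object ids")
    for o in order:
        o = int(o)
        if invalid[o]:
            continue
        row = smat[o - 1]
        index = 2
        largest: np.ndarray = row[:1]  # the singleton {o}
        while index <= n:
            prefix = row[:index]
            if invalid[prefix].any():
                break
            ok, ci = _prefix_test(rmat, row, index, n)
            if ok:
                examinations[index] = examinations.get(index, 0) + 1
                forest.merge(prefix, formed_by=f"a2:o={o}")
                largest = prefix
                index += 1
            else:
                if ci >= n:
                    break  # uninformative failure: retires the object, not charged
                examinations[index] = examinations.get(index, 0) + 1
                index = ci
        invalid[largest] = True
    return SCGRun(forest=forest, examinations=examinations, algorithm="a2", complete=False)


def scg_a3(rm: RankMatrix) -> SCGRun:
    """Minimum-index scheduled SCG; complete structure, same forest as A1.

    Every object starts with index 2.  Repeatedly, all still-active objects
    whose index equals the global minimum are examined in ascending id order:
    a success forms the cluster and bumps every member's index past the
    level, a failure raises the object's index to its candidate index, and a
    candidate index of n retires the object permanently.
    """
    n = rm.n
    forest = ClusterForest(n, labels=rm.labels)
    rmat, smat = rm.rmatrix, rm.smatrix
    examinations: dict[int, int] = {}
    index = np.full(n + 1, 2, dtype=np.int64)
    alive = np.ones(n + 1, dtype=bool)
    alive[0] = False
    levels: list[int] = []
    while alive.any():
        level = int(index[alive].min())
        levels.append(level)
        iteration_valid = alive.copy()
        for o in range(1, n + 1):
            if not (iteration_valid[o] and alive[o] and index[o] == level):
                continue
            row = smat[o - 1]
            ok, ci = _prefix_test(rmat, row, level, n)
            if ok:
                examinations[level] = examinations.get(level, 0) + 1
                members = row[:level]
                forest.merge(members, formed_by=f"a3:level={level}")
                index[members] = level + 1
                iteration_valid[members] = False
            elif ci >= n:
                alive[o] = False  # uninformative failure: retired, not charged
            else:
                examinations[level] = examinations.get(level, 0) + 1
                index[o] = ci
    return SCGRun(
        forest=forest,
        examinations=examinations,
        algorithm="a3",
        complete=True,
        levels=tuple(levels),
    )


def enumerate_all_clusters(rm: RankMatrix, max_n: int = 15) -> set[frozenset[int]]:
    """Brute-force oracle: every subset of size 2..n-1 passing the cluster test.

    Exponential in n, hence the guard; intended for verifying the algorithms
    on small instances.  The returned family (plus singletons) is laminar and
    equals the A1/A3 forest; its maximal elements are the independent
    clusters.
    """
    n = rm.n
    if n > max_n:
        raise ValueError(f"n={n} exceeds the enumeration bound max_n={max_n}")
    rmat = rm.rmatrix
    found: set[frozenset[int]] = set()
    objs = range(1, n + 1)
    for k in range(2, n):
        for combo in itertools.combinations(objs, k):
            idx = np.array(combo) - 1
            if int(rmat[np.ix_(idx, idx)].max()) <= k:
                found.add(frozenset(combo))
    return found
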