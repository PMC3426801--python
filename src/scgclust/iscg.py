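"""Iterative SCG (iSCG).

Plain SCG is deliberately stringent; when a few false positives are
tolerable in exchange for larger clusters, the procedure can be iterated:
after a pass, each independent cluster (including singletons) is collapsed
into a super-object, inter-group distances are recomputed with one of three
strategies — ``min`` (most similar cross pair, SL-like), ``avg`` (average
cross-pair distance, AL-like) or ``max`` (most distant cross pair, CL-like)
— the rank matrix is rebuilt and SCG runs again.  Iteration stops when a
pass forms no new non-singleton cluster or ``max_iter`` is reached.  The
final forest nests each pass's structure inside the next, so cluster
membership only ever grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SCGRun, scg_a3
from .forest import ClusterForest, Partition
from .ranking import ScoreMatrix, build_rank_matrix

__all__ = ["iscg", "ISCGRun"]

_STRATEGIES = ("min", "avg", "max")


@dataclass
class ISCGRun:
    """Forest accumulated over all passes plus per-pass flat partitions."""

    forest: ClusterForest
    iterations: list[Partition]
    n_iter: int

    @property
    def independent_clusters(self) -> Partition:
        return self.forest.independent_clusters()


def _group_distances(
    dist: np.ndarray,
    groups: list[frozenset[int]],
    strategy: str,
    prev: np.ndarray | None,
    prev_groups_of: list[list[int]] | None,
    avg_update: str,
) -> np.ndarray:
    """Distance matrix between super-objects."""
    m = len(groups)
    out = np.zeros((m, m))
    if strategy == "avg" and avg_update == "group" and prev is not None:
        # unweighted mean of previous-level group distances (WPGMA-flavoured)
        assert prev_groups_of is not None
        for a in range(m):
            for b in range(a + 1, m):
                block = prev[np.ix_(prev_groups_of[a], prev_groups_of[b])]
                out[a, b] = out[b, a] = float(block.mean())
        return out
    reduce = {"min": np.min, "avg": np.mean, "max": np.max}[strategy]
    idx = [np.array(sorted(g)) - 1 for g in groups]
    for a in range(m):
        for b in range(a + 1, m):
            block = dist[np.ix_(idx[a], idx[b])]
            out[a, b] = out[b, a] = float(reduce(block))
    return out


def iscg(
    scores: ScoreMatrix,
    strategy: str = "min",
    max_iter: int = 10,
    avg_update: str = "pairwise",
) -> ISCGRun:
    """Run SCG in iteration, collapsing independent clusters between passes.

    Parameters
    ----------
    scores : ScoreMatrix
        Pairwise scores over the original objects (similarities are handled
        by ranking on the negated values).
    strategy : {"min", "avg", "max"}
        How the distance between two collapsed groups is derived from their
        members' distances.
    max_iter : int
        Upper bound on the number of SCG passes (>= 1).
    avg_update : {"pairwise", "group"}
        For ``strategy="avg"`` only: average over all original cross-member
        pairs (default) or unweighted over the previous level's group
        distances.
    """
    if strategy not in _STRATEGIES:
        raise ValueError(f"strategy must be one of {_STRATEGIES}, got {strategy!r}")
    if avg_update not in ("pairwise", "group"):
        raise ValueError(f"avg_update must be 'pairwise' or 'group', got {avg_update!r}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    n = scores.n
    dist0 = scores.as_distances()
    np.fill_diagonal(dist0, 0.0)
    if scores.mask is not None and not scores.mask.all():
        worst = dist0[scores.mask].max() + 1.0 if scores.mask.any() else 1.0
        dist0 = np.where(scores.mask, dist0, worst)

    forest = ClusterForest(n, labels=scores.labels)
    groups: list[frozenset[int]] = [frozenset({i}) for i in range(1, n + 1)]
    level_dist = dist0
    iterations: list[Partition] = []
    n_iter = 0
    for _ in range(max_iter):
        m = len(groups)
        if m <= 2:
            break  # size-m clusters are disallowed, nothing can form
        rm = build_rank_matrix(ScoreMatrix(level_dist, orientation="distance"))
        run: SCGRun = scg_a3(rm)
        if not run.forest.internal_nodes():
            break  # fixed point: the pass formed nothing
        n_iter += 1
        # replay this pass's structure on the original objects
        for nd in run.forest.internal_nodes():
            members = frozenset().union(*(groups[g - 1] for g in nd.members))
            forest.merge(members, formed_by=f"iscg:iter={n_iter}:{nd.formed_by}")
        part = run.forest.independent_clusters()
        new_groups = [frozenset().union(*(groups[g - 1] for g in grp)) for grp in part.groups]
        prev_groups_of = [[gi - 1 for gi in grp] for grp in part.groups]
        iterations.append(forest.independent_clusters())
        next_dist = _group_distances(
            dist0, new_groups, strategy, level_dist, prev_groups_of, avg_update
        )
        groups = new_groups
        level_dist = next_dist
    if not iterations:
        iterations.append(forest.independent_clusters())
    return ISCGRun(forest=forest, iterations=iterations, n_iter=n_iter)
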