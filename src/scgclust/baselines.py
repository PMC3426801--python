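"""Agglomerative linkage baselines (single / complete / average).

These are the conventional hierarchical methods SCG is compared against:
complete linkage (CL) merges two groups only when the *maximum* cross-pair
distance is within the cut-off, single linkage (SL) uses the minimum and
chains aggressively, average linkage (AL) sits in between.  The merge tree is
delegated to :mod:`scipy.cluster.hierarchy`; a flat partition is obtained
either by a distance cut-off ``delta`` or by requesting ``n_clusters``
groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .forest import Partition
from .ranking import ScoreMatrix

__all__ = ["LinkageSpec", "linkage_partition"]

_METHODS = ("single", "complete", "average")


@dataclass(frozen=True)
class LinkageSpec:
    """Linkage method plus exactly one cutting rule.

    ``cutoff`` is the distance cut-off delta (> 0 in the usual case, any
    finite value accepted since perturbed distances may be negative);
    ``n_clusters`` cuts the merge tree into exactly K groups.
    """

    method: str
    cutoff: float | None = None
    n_clusters: int | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if (self.cutoff is None) == (self.n_clusters is None):
            raise ValueError("specify exactly one of cutoff or n_clusters")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


def linkage_partition(scores: ScoreMatrix | np.ndarray, spec: LinkageSpec) -> Partition:
    """Flat partition from standard agglomerative clustering.

    Requires a symmetric distance matrix (convert similarities upstream).
    In cut-off mode every within-group merge happens at a method-specific
    linkage distance <= delta; in ``n_clusters`` mode the tree is cut into
    exactly K groups (singletons count).
    """
    if isinstance(scores, ScoreMatrix):
        if scores.orientation != "distance":
            raise ValueError("linkage_partition requires distances; convert similarities first")
        if scores.mask is not None and not scores.mask.all():
            raise ValueError("linkage_partition requires a dense distance matrix")
        labels = scores.labels
        d = scores.values
    else:
        d = np.asarray(scores, dtype=float)
        labels = None
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=1e-9, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if spec.n_clusters is not None and spec.n_clusters > n:
        raise ValueError(f"n_clusters={spec.n_clusters} exceeds the number of objects {n}")
    if n == 1:
        return Partition([[1]], n=1, labels=labels)
    sym = 0.5 * (d + d.T)
    np.fill_diagonal(sym, 0.0)
    condensed = squareform(sym, checks=False)
    # Single/complete/average linkage are equivariant under a rigid shift of
    # all distances, so non-positive entries (e.g. noise-perturbed distances)
    # are shifted into the positive range and the cut-off shifted with them.
    shift = 0.0
    lo = condensed.min() if condensed.size else 0.0
    if lo <= 0:
        shift = 1.0 - lo
        condensed = condensed + shift
    Z = hierarchy.linkage(condensed, method=spec.method)
    if spec.cutoff is not None:
        codes = hierarchy.fcluster(Z, t=spec.cutoff + shift, criterion="distance")
    else:
        codes = hierarchy.fcluster(Z, t=spec.n_clusters, criterion="maxclust")
    return Partition.from_codes(codes, labels=labels)
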