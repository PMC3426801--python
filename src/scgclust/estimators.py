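"""scikit-learn style estimators wrapping the SCG machinery.

These classes make the package composable with sklearn pipelines and model
selection: construction takes hyper-parameters only, :meth:`fit` accepts
either raw coordinates (``metric="euclidean"``) or a precomputed square
score matrix (``metric="precomputed"``), and fitted state lives in
trailing-underscore attributes (``labels_``, ``n_clusters_``, ``forest_``).
The flat labels are the independent clusters; the full subcluster structure
stays available on ``forest_``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array
from scipy.spatial.distance import pdist, squareform

from .baselines import LinkageSpec, linkage_partition
from .core import scg_a1, scg_a2, scg_a3
from .iscg import iscg
from .ranking import ScoreMatrix, build_rank_matrix

__all__ = ["SCGClustering", "IterativeSCG", "LinkageClustering"]

_ALGORITHMS = {"a1": scg_a1, "a2": scg_a2, "a3": scg_a3, "scg-fast": scg_a2}


def _to_scores(X, metric: str, orientation: str) -> ScoreMatrix:
    X = check_array(X, dtype=float, ensure_min_samples=1)
    if metric == "precomputed":
        if X.shape[0] != X.shape[1]:
            raise ValueError("precomputed score matrix must be square")
        return ScoreMatrix(X, orientation=orientation)
    if metric == "euclidean":
        return ScoreMatrix(squareform(pdist(X)), orientation="distance")
    raise ValueError(f"metric must be 'euclidean' or 'precomputed', got {metric!r}")


class SCGClustering(ClusterMixin, BaseEstimator):
    """Self-consistency grouping as a clusterer.

    Parameters
    ----------
    algorithm : {"a3", "a1", "a2", "scg-fast"}
        "a1"/"a3" recover the complete subcluster structure (identical
        output; "a3" is faster); "a2" (alias "scg-fast") guarantees the
        independent clusters only.
    metric : {"euclidean", "precomputed"}
    orientation : {"distance", "similarity"}
        Meaning of a precomputed matrix; ignored for ``metric="euclidean"``.
    tie_rule : {"id"}
        Tie handling when building ranks.

    Attributes
    ----------
    labels_ : (n,) int array — independent-cluster index per object.
    n_clusters_ : number of independent clusters, singletons included.
    forest_ : :class:`~scgclust.forest.ClusterForest` with the structure.
    rank_matrix_ : the rank matrix the algorithm consumed.
    examinations_ : dict, candidate-cluster tests charged per size.

    Examples
    --------
    >>> import numpy as np
    >>> from scgclust import SCGClustering
    >>> pts = np.array([[0, 0], [0.3, 0], [10, 0], [10.3, 0], [5, 8.66], [5.3, 8.66]])
    >>> SCGClustering().fit_predict(pts)
    array([0, 0, 1, 1, 2, 2])
    """

    def __init__(
        self,
        algorithm: str = "a3",
        metric: str = "euclidean",
        orientation: str = "distance",
        tie_rule: str = "id",
    ) -> None:
        self.algorithm = algorithm
        self.metric = metric
        self.orientation = orientation
        self.tie_rule = tie_rule

    def fit(self, X, y=None):
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"algorithm must be one of {sorted(_ALGORITHMS)}")
        scores = _to_scores(X, self.metric, self.orientation)
        self.n_features_in_ = np.asarray(X).shape[1]
        self.rank_matrix_ = build_rank_matrix(scores, tie_rule=self.tie_rule)
        run = _ALGORITHMS[self.algorithm](self.rank_matrix_)
        self.run_ = run
        self.forest_ = run.forest
        part = run.independent_clusters
        self.labels_ = part.codes()
        self.n_clusters_ = part.n_groups
        self.examinations_ = dict(run.examinations)
        return self


class IterativeSCG(ClusterMixin, BaseEstimator):
    """Iterated SCG: collapse independent clusters and re-cluster.

    See :func:`scgclust.iscg.iscg` for the strategy semantics.  ``labels_``
    holds the final flat partition; ``history_`` the partition after every
    pass.
    """

    def __init__(
        self,
        strategy: str = "min",
        max_iter: int = 10,
        avg_update: str = "pairwise",
        metric: str = "euclidean",
        orientation: str = "distance",
    ) -> None:
        self.strategy = strategy
        self.max_iter = max_iter
        self.avg_update = avg_update
        self.metric = metric
        self.orientation = orientation

    def fit(self, X, y=None):
        scores = _to_scores(X, self.metric, self.orientation)
        self.n_features_in_ = np.asarray(X).shape[1]
        run = iscg(
            scores,
            strategy=self.strategy,
            max_iter=self.max_iter,
            avg_update=self.avg_update,
        )
        self.run_ = run
        self.forest_ = run.forest
        part = run.independent_clusters
        self.labels_ = part.codes()
        self.n_clusters_ = part.n_groups
        self.n_iter_ = run.n_iter
        self.history_ = list(run.iterations)
        return self


class LinkageClustering(ClusterMixin, BaseEstimator):
    """Single/complete/average linkage with a distance cut-off or target K."""

    def __init__(
        self,
        method: str = "complete",
        cutoff: float | None = None,
        n_clusters: int | None = None,
        metric: str = "euclidean",
    ) -> None:
        self.method = method
        self.cutoff = cutoff
        self.n_clusters = n_clusters
        self.metric = metric

    def fit(self, X, y=None):
        spec = LinkageSpec(self.method, cutoff=self.cutoff, n_clusters=self.n_clusters)
        scores = _to_scores(X, self.metric, "distance")
        self.n_features_in_ = np.asarray(X).shape[1]
        part = linkage_partition(scores, spec)
        self.labels_ = part.codes()
        self.n_clusters_ = part.n_groups
        return self
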