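"""Pair-based clustering quality against a reference partition.

Every within-cluster unordered pair is a claim that two objects belong
together; scoring a clustering against a reference (e.g. expert fold
assignments) reduces to counting how many of those claims the reference
confirms.  A pair is *incorrect* when its two members sit in different
reference groups; singletons contribute no pairs, so maximal fragmentation
scores zero incorrect pairs by construction.  Counting is combinatorial (via
the group-by-reference contingency table), never by materialising pair
lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skmetrics

from .forest import Partition

__all__ = [
    "count_pair_errors",
    "clustering_similarity",
    "size_histogram",
    "EvaluationReport",
    "evaluate_partition",
]

SIZE_BUCKETS = ("1", "2", "3", "4", "5", ">5")


def _check_same_objects(p1: Partition, p2: Partition) -> None:
    if p1.n != p2.n:
        raise ValueError(f"partitions cover different object sets ({p1.n} vs {p2.n} objects)")
    if p1.labels is not None and p2.labels is not None and p1.labels != p2.labels:
        raise ValueError("partitions cover differently labelled object sets")


def _contingency(p1: Partition, p2: Partition) -> np.ndarray:
    c1, c2 = p1.codes(), p2.codes()
    table = np.zeros((p1.n_groups, p2.n_groups), dtype=np.int64)
    np.add.at(table, (c1, c2), 1)
    return table


def _pairs(counts: np.ndarray) -> np.ndarray:
    return counts * (counts - 1) // 2


def count_pair_errors(partition: Partition, reference: Partition) -> tuple[int, int]:
    """(correct, incorrect) within-cluster pair counts of *partition*.

    A pair is correct iff both members share a reference group.
    """
    _check_same_objects(partition, reference)
    table = _contingency(partition, reference)
    total = int(_pairs(table.sum(axis=1)).sum())
    correct = int(_pairs(table).sum())
    return correct, total - correct


def clustering_similarity(p1: Partition, p2: Partition, metric: str = "jaccard") -> float:
    """Similarity of two partitions of the same objects, in [0, 1].

    ``"jaccard"`` (default) is the Jaccard index of the two within-cluster
    pair sets: 1.0 iff the pair sets are identical (two all-singleton
    partitions are identical), 0.0 when they are disjoint and non-empty.
    ``"rand"`` and ``"adjusted_rand"`` delegate to scikit-learn (note the
    adjusted index may be negative).
    """
    _check_same_objects(p1, p2)
    if metric == "jaccard":
        table = _contingency(p1, p2)
        both = int(_pairs(table).sum())
        in1 = int(_pairs(table.sum(axis=1)).sum())
        in2 = int(_pairs(table.sum(axis=0)).sum())
        union = in1 + in2 - both
        return 1.0 if union == 0 else both / union
    if metric == "rand":
        return float(_skmetrics.rand_score(p1.codes(), p2.codes()))
    if metric == "adjusted_rand":
        return float(_skmetrics.adjusted_rand_score(p1.codes(), p2.codes()))
    raise ValueError(f"unknown metric: {metric!r}")


def size_histogram(partition: Partition) -> dict[str, int]:
    """Cluster counts by size: buckets "1".."5" plus ">5" for everything larger."""
    hist = dict.fromkeys(SIZE_BUCKETS, 0)
    for s in partition.sizes():
        hist[str(s) if s <= 5 else ">5"] += 1
    return hist


@dataclass
class EvaluationReport:
    """Summary of a flat clustering against a reference partition."""

    n_clusters: int
    n_non_singleton: int
    correct_pairs: int
    incorrect_pairs: int
    percent_correct: float
    percent_incorrect: float
    size_histogram: dict[str, int] = field(default_factory=dict)

    @property
    def total_pairs(self) -> int:
        return self.correct_pairs + self.incorrect_pairs

    def to_text(self) -> str:
        lines = [
            f"Total number of clusters\t{self.n_clusters}",
            f"Number of non-singleton clusters\t{self.n_non_singleton}",
            f"Number of incorrect pairs\t{self.incorrect_pairs}",
            f"Percentage of incorrect pairs\t({self.percent_incorrect:.1f})",
            f"Number of correct pairs\t{self.correct_pairs}",
            f"Percentage of correct pairs\t({self.percent_correct:.1f})",
            "Cluster size histogram\t"
            + " ".join(f"{k}:{self.size_histogram.get(k, 0)}" for k in SIZE_BUCKETS),
        ]
        return "\n".join(lines)


def evaluate_partition(partition: Partition, reference: Partition) -> EvaluationReport:
    """Build the full :class:`EvaluationReport` for *partition* vs *reference*."""
    correct, incorrect = count_pair_errors(partition, reference)
    total = correct + incorrect
    return EvaluationReport(
        n_clusters=partition.n_groups,
        n_non_singleton=len(partition.non_singletons()),
        correct_pairs=correct,
        incorrect_pairs=incorrect,
        percent_correct=100.0 * correct / total if total else 0.0,
        percent_incorrect=100.0 * incorrect / total if total else 0.0,
        size_histogram=size_histogram(partition),
    )
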