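"""Rank matrices from distance or similarity data.

Self-consistency grouping (SCG) never consumes raw scores: its sole input is
the *rank matrix*.  For an object ``x``, every other object ``y`` receives the
asymmetric rank ``rank(x, y) = p`` when exactly ``p - 1`` objects (including
``x`` itself) are more similar to ``x`` than ``y`` is.  Each row of the rank
matrix is therefore a permutation of ``1..n`` with ``rank(x, x) = 1``, and
the relation is deliberately *not* symmetric: ``y`` may be the nearest
neighbour of ``x`` while ``x`` sits far down the list of ``y``.

Because only the ordering of scores matters, ranks are invariant under any
strictly monotone transformation of the distances — a property the test suite
asserts.

Two companions are kept for every rank matrix:

``rmatrix``
    ``rmatrix[i, j]`` is ``rank(i, j)`` (1-based object ids).
``smatrix``
    the row-wise inverse permutation: ``smatrix[i, k]`` is the object holding
    rank ``k`` in row ``i``, so ``smatrix[i, 1] = i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ObjectSet",
    "ScoreMatrix",
    "RankMatrix",
    "build_rank_matrix",
    "densify_pair_scores",
]

_ORIENTATIONS = ("distance", "similarity")


@dataclass(frozen=True)
class ObjectSet:
    """An ordered collection of uniquely labelled objects.

    Internal object ids are 1-based positions in ``labels``; all public I/O
    speaks labels, all algorithmic code speaks ids.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("ObjectSet requires at least one object")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("object labels must be unique")
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    def id_of(self, label: str) -> int:
        """Return the 1-based internal id of *label*."""
        try:
            return self.labels.index(str(label)) + 1
        except ValueError:
            raise KeyError(f"unknown object label: {label!r}") from None

    @classmethod
    def numbered(cls, n: int) -> "ObjectSet":
        """Objects labelled ``"1" .. "n"``."""
        return cls(tuple(str(i) for i in range(1, n + 1)))


@dataclass(eq=False)
class ScoreMatrix:
    """A square table of pairwise distances or similarities.

    Parameters
    ----------
    values : (n, n) float array
        ``values[i, j]`` scores the ordered pair ``(i, j)``.  Asymmetric
        tables are accepted as-is; the rank definition is asymmetric anyway.
    orientation : {"distance", "similarity"}
        Whether small or large values mean "close".
    objects : ObjectSet
        Labels for the rows/columns.
    mask : (n, n) bool array, optional
        ``True`` where a score was observed.  Missing off-diagonal entries
        are ranked strictly worse than every observed score.
    """

    values: np.ndarray
    orientation: str = "distance"
    objects: ObjectSet | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"score matrix must be square, got shape {self.values.shape}")
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {self.orientation!r}")
        if self.objects is None:
            self.objects = ObjectSet.numbered(self.values.shape[0])
        if self.objects.n != self.values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.objects.labels

    def as_distances(self) -> np.ndarray:
        """Values on a distance scale (similarities are negated)."""
        if self.orientation == "distance":
            return self.values.copy()
        return -self.values

    def is_symmetric(self, rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, self.values.T, rtol=rtol, atol=atol))


@dataclass(eq=False)
class RankMatrix:
    """The pair (``rmatrix``, ``smatrix``) that SCG operates on.

    Entries of both arrays are 1-based; ``rmatrix`` is indexed
    ``rmatrix[i - 1, j - 1]`` for objects ``i`` and ``j``.
    """

    rmatrix: np.ndarray
    objects: ObjectSet | None = None
    smatrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rmatrix = np.asarray(self.rmatrix, dtype=np.int64)
        n = self.rmatrix.shape[0]
        if self.rmatrix.ndim != 2 or self.rmatrix.shape != (n, n):
            raise ValueError("rmatrix must be square")
        if self.objects is None:
            self.objects = ObjectSet.numbered(n)
        if self.objects.n != n:
            raise ValueError("label count does not match rmatrix size")
        expect = np.arange(1, n + 1)
        if not np.array_equal(np.sort(self.rmatrix, axis=1), np.broadcast_to(expect, (n, n))):
            raise ValueError("every rmatrix row must be a permutation of 1..n")
        if self.smatrix is None:
            self.smatrix = self._invert(self.rmatrix)
        else:
            self.smatrix = np.asarray(self.smatrix, dtype=np.int64)
        self.validate()

    @staticmethod
    def _invert(rmatrix: np.ndarray) -> np.ndarray:
        n = rmatrix.shape[0]
        smatrix = np.empty_like(rmatrix)
        rows = np.arange(n)[:, None]
        smatrix[rows, rmatrix - 1] = np.arange(1, n + 1)[None, :]
        return smatrix

    def validate(self) -> None:
        """Assert every structural invariant of a rank matrix."""
        n = self.n
        expect = np.arange(1, n + 1)
        if not np.array_equal(np.sort(self.rmatrix, axis=1), np.broadcast_to(expect, (n, n))):
            raise ValueError("every rmatrix row must be a permutation of 1..n")
        if not np.array_equal(np.diagonal(self.rmatrix), np.ones(n, dtype=np.int64)):
            raise ValueError("rmatrix diagonal must be 1 (self is most similar)")
        if not np.array_equal(self.smatrix[:, 0], expect):
            raise ValueError("smatrix[i, 1] must equal i")
        if not np.array_equal(self._invert(self.rmatrix), self.smatrix):
            raise ValueError("smatrix is not the row-wise inverse of rmatrix")

    @property
    def n(self) -> int:
        return self.rmatrix.shape[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.objects.labels

    def rank(self, x: int, y: int) -> int:
        """``rank(x, y)`` for 1-based object ids."""
        return int(self.rmatrix[x - 1, y - 1])

    def row_order(self, x: int) -> np.ndarray:
        """Objects (1-based) in increasing rank order with respect to ``x``."""
        return self.smatrix[x - 1].copy()


def build_rank_matrix(scores: ScoreMatrix, tie_rule: str = "id") -> RankMatrix:
    """Convert a score matrix into the asymmetric rank matrix.

    Row ``i`` ranks all objects by increasing distance (or decreasing
    similarity) to object ``i``; the object itself is forced to rank 1
    regardless of the stored self-score.  Masked-out (missing) entries rank
    strictly worse than every observed score.

    Parameters
    ----------
    scores : ScoreMatrix
    tie_rule : {"id"}
        How equal scores are ordered.  ``"id"`` breaks ties by ascending
        object id, which is deterministic and the only supported policy.

    Raises
    ------
    ValueError
        On non-square input, a non-finite score outside the missing mask, or
        an unknown tie rule.
    """
    if tie_rule != "id":
        raise ValueError(f"unknown tie_rule: {tie_rule!r}")
    off_diag = ~np.eye(scores.n, dtype=bool)
    present = off_diag if scores.mask is None else (off_diag & scores.mask)
    if not np.all(np.isfinite(scores.values[present])):
        raise ValueError("scores contain non-finite values outside the missing mask")
    key = scores.values.astype(float, copy=True)
    if scores.orientation == "similarity":
        key = -key
    key[~present & off_diag] = np.inf  # missing pairs rank worse than anything observed
    np.fill_diagonal(key, -np.inf)  # self is always rank 1
    order0 = np.argsort(key, axis=1, kind="stable")  # stable sort == ties by ascending id
    smatrix = (order0 + 1).astype(np.int64)
    n = scores.n
    rmatrix = np.empty((n, n), dtype=np.int64)
    rows = np.arange(n)[:, None]
    rmatrix[rows, order0] = np.arange(1, n + 1)[None, :]
    return RankMatrix(rmatrix, objects=scores.objects, smatrix=smatrix)


def densify_pair_scores(
    pairs: Iterable[tuple[str, str, float]],
    orientation: str = "similarity",
    objects: ObjectSet | Sequence[str] | None = None,
    worst_policy: str = "mask",
    strict_duplicates: bool = False,
) -> ScoreMatrix:
    """Build a full :class:`ScoreMatrix` from a sparse ``(id1, id2, score)`` list.

    Absent pairs are treated as strictly worse than every observed score so
    that they can never enter a cluster by accident: with
    ``worst_policy="mask"`` they are carried in the missing mask (and ranked
    last by :func:`build_rank_matrix`); with ``worst_policy="fill"`` they are
    replaced by a numeric value one unit worse than the worst observation.

    A record ``(a, b, s)`` fills both ordered entries unless the opposite
    direction is listed explicitly with its own score, in which case each
    direction keeps its own value (asymmetric input preserved as-is).
    Duplicate records for the same ordered pair keep the better score with a
    warning, or raise when ``strict_duplicates`` is set and the scores differ.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    if worst_policy not in ("mask", "fill"):
        raise ValueError(f"unknown worst_policy: {worst_policy!r}")
    pairs = [(str(a), str(b), float(s)) for a, b, s in pairs]
    if objects is None:
        seen: list[str] = []
        for a, b, _ in pairs:
            for lab in (a, b):
                if lab not in seen:
                    seen.append(lab)
        if not seen:
            raise ValueError("cannot infer an object set from an empty pair list")
        objects = ObjectSet(tuple(sorted(seen)))
    elif not isinstance(objects, ObjectSet):
        objects = ObjectSet(tuple(objects))

    better = max if orientation == "similarity" else min
    explicit: dict[tuple[int, int], float] = {}
    for a, b, s in pairs:
        key = (objects.id_of(a), objects.id_of(b))
        if key[0] == key[1]:
            continue  # self scores are implied (self is always rank 1)
        if key in explicit and explicit[key] != s:
            if strict_duplicates:
                raise ValueError(f"conflicting duplicate scores for pair {a!r}, {b!r}")
            warnings.warn(
                f"duplicate pair ({a!r}, {b!r}) with conflicting scores; keeping the better one",
                stacklevel=2,
            )
            s = better(s, explicit[key])
        explicit[key] = s

    n = objects.n
    values = np.full((n, n), np.nan)
    mask = np.eye(n, dtype=bool)
    for (i, j), s in explicit.items():
        values[i - 1, j - 1] = s
        mask[i - 1, j - 1] = True
    for (i, j), s in explicit.items():
        if (j, i) not in explicit:
            values[j - 1, i - 1] = s
            mask[j - 1, i - 1] = True
    observed = values[mask & ~np.eye(n, dtype=bool)]
    if orientation == "similarity":
        diag = (observed.max() + 1.0) if observed.size else 1.0
        worst = (observed.min() - 1.0) if observed.size else 0.0
    else:
        diag = 0.0
        worst = (observed.max() + 1.0) if observed.size else 1.0
    np.fill_diagonal(values, diag)
    if worst_policy == "fill":
        values[~mask] = worst
        return ScoreMatrix(values, orientation=orientation, objects=objects)
    return ScoreMatrix(values, orientation=orientation, objects=objects, mask=mask)
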