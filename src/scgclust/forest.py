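"""Laminar cluster forests and flat partitions.

SCG produces a *laminar* family of clusters: any two clusters are either
disjoint or nested.  The family is therefore naturally stored as a forest
whose leaves are the n objects, whose internal nodes are clusters, and whose
roots are the independent clusters (plus singleton objects that belong to no
cluster).  Subcluster management follows the scheme of the algorithms: when a
new cluster forms, the current roots of its members become the children of a
freshly created root.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .ranking import ScoreMatrix

__all__ = ["LaminarityError", "ForestNode", "ClusterForest", "Partition"]


class LaminarityError(ValueError):
    """A requested merge would straddle an existing cluster."""


@dataclass
class ForestNode:
    id: int
    members: frozenset[int]
    children: tuple[int, ...] = ()
    formed_by: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Partition:
    """A flat assignment of the objects ``1..n`` to disjoint groups.

    Groups are stored sorted by their smallest member, so two partitions with
    the same group contents compare (and hash) equal regardless of input
    order.  Singletons are ordinary groups.
    """

    def __init__(
        self,
        groups: Iterable[Iterable[int]],
        n: int | None = None,
        labels: Sequence[str] | None = None,
    ) -> None:
        gs = sorted((frozenset(int(m) for m in g) for g in groups), key=min)
        union: set[int] = set()
        total = 0
        for g in gs:
            if not g:
                raise ValueError("empty group in partition")
            union |= g
            total += len(g)
        if total != len(union):
            raise ValueError("groups overlap")
        if n is None:
            n = len(union)
        if union != set(range(1, n + 1)):
            raise ValueError("groups must partition the objects 1..n")
        self.groups: tuple[frozenset[int], ...] = tuple(gs)
        self.n = n
        self.labels: tuple[str, ...] | None = tuple(labels) if labels is not None else None
        if self.labels is not None and len(self.labels) != n:
            raise ValueError("label count does not match partition size")

    @classmethod
    def from_codes(cls, codes: Sequence[int], labels: Sequence[str] | None = None) -> "Partition":
        """Build from a per-object group code array (sklearn ``labels_`` style)."""
        codes = np.asarray(codes)
        groups: dict[object, set[int]] = {}
        for i, c in enumerate(codes, start=1):
            groups.setdefault(c.item() if hasattr(c, "item") else c, set()).add(i)
        return cls(groups.values(), n=len(codes), labels=labels)

    @classmethod
    def singletons(cls, n: int, labels: Sequence[str] | None = None) -> "Partition":
        return cls(([i] for i in range(1, n + 1)), n=n, labels=labels)

    def codes(self) -> np.ndarray:
        """0-based group index per object, groups ordered by smallest member."""
        out = np.empty(self.n, dtype=np.int64)
        for gi, g in enumerate(self.groups):
            for m in g:
                out[m - 1] = gi
        return out

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    def non_singletons(self) -> tuple[frozenset[int], ...]:
        return tuple(g for g in self.groups if len(g) > 1)

    def group_of(self, obj: int) -> frozenset[int]:
        for g in self.groups:
            if obj in g:
                return g
        raise KeyError(obj)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and self.n == other.n and self.groups == other.groups

    def __hash__(self) -> int:
        return hash((self.n, self.groups))

    def __repr__(self) -> str:
        gs = ", ".join("{" + ",".join(map(str, sorted(g))) + "}" for g in self.groups)
        return f"Partition({gs})"


def _quote_newick(label: str) -> str:
    if any(c in label for c in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


class ClusterForest:
    """Forest of nested clusters over objects ``1..n``.

    Leaves carry node ids ``1..n`` (equal to the object ids); internal nodes
    are numbered from ``n + 1`` in creation order.
    """

    def __init__(self, n: int, labels: Sequence[str] | None = None) -> None:
        if n < 1:
            raise ValueError("forest needs at least one object")
        self.n = n
        self.labels: tuple[str, ...] = (
            tuple(labels) if labels is not None else tuple(str(i) for i in range(1, n + 1))
        )
        if len(self.labels) != n:
            raise ValueError("label count does not match n")
        self._nodes: dict[int, ForestNode] = {
            i: ForestNode(id=i, members=frozenset({i})) for i in range(1, n + 1)
        }
        self._parent: dict[int, int] = {}
        self._next_id = n + 1

    # -- structure queries -------------------------------------------------
    def node(self, node_id: int) -> ForestNode:
        return self._nodes[node_id]

    def root_of(self, node_or_obj: int) -> int:
        nid = node_or_obj
        if nid not in self._nodes:
            raise KeyError(f"unknown node id {nid}")
        while nid in self._parent:
            nid = self._parent[nid]
        return nid

    def roots(self) -> list[int]:
        rs = [nid for nid in self._nodes if nid not in self._parent]
        return sorted(rs, key=lambda nid: min(self._nodes[nid].members))

    def internal_nodes(self) -> list[ForestNode]:
        """Non-leaf nodes in creation order."""
        return [nd for nid, nd in sorted(self._nodes.items()) if nd.children]

    def cluster_family(self) -> frozenset[frozenset[int]]:
        """The member sets of all (non-singleton) clusters in the forest."""
        return frozenset(nd.members for nd in self.internal_nodes())

    def independent_clusters(self) -> Partition:
        """Root member sets; singletons included as their own groups."""
        return Partition(
            (self._nodes[r].members for r in self.roots()), n=self.n, labels=self.labels
        )

    # -- construction ------------------------------------------------------
    def merge(self, members: Iterable[int], formed_by: str | None = None) -> int:
        """Create a new root whose children are the current roots of *members*.

        Existing roots fully contained in *members* are attached intact, so
        previously found subclusters are preserved.  Raises
        :class:`LaminarityError` if *members* straddles an existing root, and
        ``ValueError`` for a set of size < 2 or >= n.
        """
        members = frozenset(int(m) for m in members)
        if not members <= set(range(1, self.n + 1)):
            raise ValueError("member ids out of range")
        if len(members) < 2:
            raise ValueError("a merged cluster needs at least two members")
        if len(members) >= self.n and self.n > 1:
            raise ValueError("a cluster of size n is disallowed")
        root_ids = sorted({self.root_of(m) for m in members}, key=lambda r: min(self._nodes[r].members))
        covered: set[int] = set()
        for r in root_ids:
            covered |= self._nodes[r].members
        if covered != members:
            raise LaminarityError(
                f"merge of {sorted(members)} straddles existing cluster(s) {sorted(covered - members)}"
            )
        if len(root_ids) == 1:
            return root_ids[0]  # the cluster already exists
        new_id = self._next_id
        self._next_id += 1
        self._nodes[new_id] = ForestNode(
            id=new_id, members=members, children=tuple(root_ids), formed_by=formed_by
        )
        for r in root_ids:
            self._parent[r] = new_id
        return new_id

    @classmethod
    def from_clusters(
        cls, n: int, clusters: Iterable[Iterable[int]], labels: Sequence[str] | None = None
    ) -> "ClusterForest":
        """Build the forest of a laminar cluster family (smallest first)."""
        forest = cls(n, labels=labels)
        for members in sorted((frozenset(c) for c in clusters), key=lambda c: (len(c), min(c))):
            forest.merge(members, formed_by="from_clusters")
        return forest

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check laminarity / member-union invariants; raise on violation."""
        leaves = {nid for nid, nd in self._nodes.items() if nd.is_leaf}
        if leaves != set(range(1, self.n + 1)):
            raise ValueError("leaves must be exactly the objects 1..n")
        for nd in self.internal_nodes():
            if len(nd.children) < 2:
                raise ValueError(f"internal node {nd.id} has fewer than two children")
            union: set[int] = set()
            total = 0
            for c in nd.children:
                child = self._nodes[c]
                if self._parent.get(c) != nd.id:
                    raise ValueError("broken parent link")
                union |= child.members
                total += len(child.members)
            if total != len(union):
                raise ValueError(f"children of node {nd.id} overlap")
            if union != nd.members:
                raise ValueError(f"member set of node {nd.id} is not the union of its children")
            if self.n > 1 and nd.size >= self.n:
                raise ValueError("cluster of size n present in forest")

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ClusterForest)
            and self.n == other.n
            and self.cluster_family() == other.cluster_family()
        )

    def __hash__(self) -> int:  # pragma: no cover - forests are rarely hashed
        return hash((self.n, self.cluster_family()))

    # -- export ------------------------------------------------------------
    def _newick_node(self, nid: int) -> str:
        nd = self._nodes[nid]
        if nd.is_leaf:
            return _quote_newick(self.labels[nid - 1])
        parts = sorted(nd.children, key=lambda c: min(self._nodes[c].members))
        return "(" + ",".join(self._newick_node(c) for c in parts) + ")"

    def to_newick(self) -> str:
        """One ';'-terminated Newick tree per root, newline-separated."""
        return "\n".join(self._newick_node(r) + ";" for r in self.roots())

    def nesting_paths(self) -> dict[int, str]:
        """Per-object path ``root/child/...`` locating its innermost cluster.

        Roots are numbered 1.. in order of smallest member; at each level the
        internal children are numbered 1.. the same way.  An object directly
        under a root (or a singleton root) gets the root's number alone.
        """
        paths: dict[int, str] = {}

        def walk(nid: int, prefix: str) -> None:
            nd = self._nodes[nid]
            for obj in nd.members:
                paths[obj] = prefix
            internal = [c for c in sorted(nd.children, key=lambda c: min(self._nodes[c].members))
                        if self._nodes[c].children]
            for j, c in enumerate(internal, start=1):
                walk(c, f"{prefix}/{j}")

        for k, r in enumerate(self.roots(), start=1):
            walk(r, str(k))
        return paths

    def clusters_by_diameter(self, scores: ScoreMatrix) -> list[tuple[ForestNode, float]]:
        """All non-singleton clusters, best (smallest diameter) first.

        The diameter of a cluster is the maximum pairwise distance between
        its members (similarities are negated); ties break by ascending
        smallest member id.
        """
        if scores.n != self.n:
            raise ValueError("score matrix size does not match forest")
        dist = scores.as_distances()
        ranked: list[tuple[ForestNode, float]] = []
        for nd in self.internal_nodes():
            idx = np.array(sorted(nd.members)) - 1
            sub = dist[np.ix_(idx, idx)]
            ranked.append((nd, float(np.max(sub))))
        ranked.sort(key=lambda t: (t[1], min(t[0].members)))
        return ranked
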