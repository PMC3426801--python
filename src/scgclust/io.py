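"""File readers and writers: labelled square matrices, pair lists,
reference partitions, cluster tables and Newick trees.

TSV is the default dialect; files ending in ``.csv`` are read/written
comma-separated.  Labels are preserved exactly as given; internal 1-based
ids never appear in outputs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .forest import ClusterForest, Partition
from .ranking import ObjectSet, ScoreMatrix

__all__ = [
    "read_square_matrix",
    "write_square_matrix",
    "read_pair_list",
    "read_partition",
    "write_partition",
    "write_clusters_tsv",
    "write_newick",
]


def _sep_for(path: str) -> str:
    return "," if os.path.splitext(str(path))[1].lower() == ".csv" else "\t"


def read_square_matrix(path: str, orientation: str = "distance") -> ScoreMatrix:
    """Read a labelled square matrix (labels in first row and first column)."""
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed matrix file ({exc})") from exc
    row_labels = [str(l) for l in df.index]
    col_labels = [str(c) for c in df.columns]
    if len(set(row_labels)) != len(row_labels):
        raise ValueError(f"{path}: duplicate row labels")
    if row_labels != col_labels:
        raise ValueError(f"{path}: row labels and column labels differ")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
        raise ValueError(f"{path}: non-numeric cells in column(s) {list(bad)}")
    return ScoreMatrix(values.astype(float), orientation=orientation,
                       objects=ObjectSet(tuple(row_labels)))


def write_square_matrix(scores: ScoreMatrix, path: str, float_format: str = "%.10g") -> None:
    df = pd.DataFrame(scores.values, index=scores.labels, columns=scores.labels)
    df.to_csv(path, sep=_sep_for(path), float_format=float_format)


def read_pair_list(path: str) -> list[tuple[str, str, float]]:
    """Read a 3-column ``id1 <TAB> id2 <TAB> score`` file ('#' comments)."""
    df = pd.read_csv(
        path, sep=_sep_for(path), comment="#", header=None,
        names=["id1", "id2", "score"], dtype={"id1": str, "id2": str},
    )
    if df["score"].isna().any() or not np.issubdtype(df["score"].dtype, np.number):
        raise ValueError(f"{path}: non-numeric or missing scores in pair list")
    return [(str(a), str(b), float(s)) for a, b, s in df.itertuples(index=False)]


def read_partition(path: str, objects: ObjectSet | None = None) -> Partition:
    """Read a 2-column ``object <TAB> group`` table.

    When *objects* is given, rows are mapped onto that object set (every
    object must appear exactly once); otherwise objects are taken in file
    order.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", header=None,
                     names=["object", "group"], dtype=str)
    labels = [str(l) for l in df["object"]]
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: object listed more than once")
    if objects is None:
        objects = ObjectSet(tuple(labels))
    elif set(labels) != set(objects.labels):
        raise ValueError(f"{path}: object labels do not match the expected object set")
    groups: dict[str, set[int]] = {}
    for lab, grp in zip(df["object"], df["group"]):
        groups.setdefault(str(grp), set()).add(objects.id_of(str(lab)))
    return Partition(groups.values(), n=objects.n, labels=objects.labels)


def write_partition(partition: Partition, path: str) -> None:
    labels = partition.labels or tuple(str(i) for i in range(1, partition.n + 1))
    codes = partition.codes()
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{lab}\t{codes[i] + 1}\n")


def write_clusters_tsv(forest_or_partition: ClusterForest | Partition, path) -> None:
    """Cluster table: object label, root/group id, nesting path."""
    close = False
    if isinstance(path, (str, os.PathLike)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("object\tcluster\tpath\n")
        if isinstance(forest_or_partition, ClusterForest):
            forest = forest_or_partition
            paths = forest.nesting_paths()
            for obj in range(1, forest.n + 1):
                root = paths[obj].split("/")[0]
                fh.write(f"{forest.labels[obj - 1]}\t{root}\t{paths[obj]}\n")
        else:
            part = forest_or_partition
            labels = part.labels or tuple(str(i) for i in range(1, part.n + 1))
            codes = part.codes()
            for i, lab in enumerate(labels):
                fh.write(f"{lab}\t{codes[i] + 1}\t{codes[i] + 1}\n")
    finally:
        if close:
            fh.close()


def write_newick(forest: ClusterForest, path) -> None:
    text = forest.to_newick() + "\n"
    if isinstance(path, (str, os.PathLike)):
        with open(path, "w") as fh:
            fh.write(text)
    else:
        path.write(text)
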