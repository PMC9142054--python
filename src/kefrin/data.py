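"""Domain containers and plain-text I/O for feature-rich networks.

A feature-rich (node-attributed) network couples an N x V node-by-feature
table with an N x N node-by-node link matrix over the same node set.  The
containers here fix a single canonical node order — the order of the feature
table — and everything downstream (standardization, clustering, evaluation)
indexes into that order.  The network is reindexed to it on read.

File formats are deliberately plain: delimited feature tables with a header
row and a leading node-id column, networks as either a dense delimited matrix
(with matching header/row ids) or a weighted edge list, and partitions as a
two-column ``node_id <tab> label`` file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

QUANTITATIVE = "quantitative"
CATEGORICAL = "categorical"


@dataclass
class FeatureMatrix:
    """Node-by-feature table with per-column kind tags.

    ``values`` is an N x V array; columns tagged ``categorical`` hold raw
    string labels awaiting one-hot encoding, columns tagged ``quantitative``
    hold floats.  After encoding/standardization all columns are floats.
    """

    values: np.ndarray
    node_ids: list[str]
    feature_names: list[str]
    feature_kinds: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        n, v = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 nodes")
        if v < 1:
            raise ValueError("need at least 1 feature")
        if len(self.node_ids) != n:
            raise ValueError("node_ids length mismatch")
        if len(set(self.node_ids)) != n:
            raise ValueError("node ids must be unique")
        if len(self.feature_names) != v or len(self.feature_kinds) != v:
            raise ValueError("feature metadata length mismatch")
        for kind in self.feature_kinds:
            if kind not in (QUANTITATIVE, CATEGORICAL):
                raise ValueError(f"unknown feature kind {kind!r}")
        if self.values.dtype.kind == "f" and not np.isfinite(self.values).all():
            raise ValueError("missing or non-finite feature values are not supported")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def has_categorical(self) -> bool:
        return CATEGORICAL in self.feature_kinds

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_ids, columns=self.feature_names)


@dataclass
class NetworkMatrix:
    """Square link-weight matrix aligned to a FeatureMatrix's node order."""

    values: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("network matrix must be square")
        if len(self.node_ids) != self.values.shape[0]:
            raise ValueError("node_ids length mismatch")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite link weights are not supported")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.allclose(self.values, self.values.T))


@dataclass
class Partition:
    """Hard partition of N nodes into K clusters, labels in [0, K)."""

    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("labels out of range [0, k)")

    @classmethod
    def from_labels(cls, labels: Sequence[int]) -> "Partition":
        labels = np.asarray(labels, dtype=int)
        return cls(labels=labels, k=int(labels.max()) + 1 if labels.size else 1)

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class CommunityCenters:
    """Two-fold community centers: K x V feature centers C and K x N
    network centers Lambda (per-community vector of link intensities)."""

    C: np.ndarray
    Lam: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.Lam = np.asarray(self.Lam, dtype=float)
        if self.C.ndim != 2 or self.Lam.ndim != 2:
            raise ValueError("centers must be 2-D")
        if self.C.shape[0] != self.Lam.shape[0]:
            raise ValueError("C and Lambda must have the same number of rows")

    @property
    def k(self) -> int:
        return self.C.shape[0]

    def copy(self) -> "CommunityCenters":
        return CommunityCenters(self.C.copy(), self.Lam.copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path, default: str | None) -> str:
    if default is not None:
        return default
    with open(path, newline="") as fh:
        sample = fh.readline()
    return "\t" if sample.count("\t") >= sample.count(",") else ","


def read_features(path: str | Path, delimiter: str | None = None) -> FeatureMatrix:
    """Read a delimited feature table: header row, first column node ids.

    Column kinds are inferred: a column whose every entry parses as a float
    is quantitative; anything else is categorical and its raw labels are kept
    for later one-hot encoding.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=delim, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty feature table in {path}")
    ids = [str(i) for i in df.index]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate node ids in {path}")
    if (df == "").any().any():
        raise ValueError(f"missing feature values in {path}")

    kinds: list[str] = []
    columns: list[np.ndarray] = []
    for name in df.columns:
        col = df[name]
        try:
            columns.append(col.astype(float).to_numpy())
            kinds.append(QUANTITATIVE)
        except ValueError:
            columns.append(col.to_numpy(dtype=object))
            kinds.append(CATEGORICAL)
    dtype = float if all(k == QUANTITATIVE for k in kinds) else object
    values = np.column_stack(columns).astype(dtype)
    return FeatureMatrix(values, ids, [str(c) for c in df.columns], kinds)


def read_network(
    path: str | Path,
    node_ids: Sequence[str],
    format: str = "edgelist",
    directed: bool = False,
    sum_duplicates: bool = False,
    delimiter: str | None = None,
) -> NetworkMatrix:
    """Read a network as an edge list or dense matrix, in the given node order.

    Edge-list rows are ``source target [weight]`` (weight defaults to 1).
    Undirected input is symmetrized: for each listed edge the two mirror
    entries are set to its weight, later occurrences overwriting earlier
    ones unless ``sum_duplicates`` accumulates them.  Absent pairs are 0.
    """
    path = Path(path)
    node_ids = [str(i) for i in node_ids]
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    if format == "matrix":
        delim = _sniff_delimiter(path, delimiter)
        df = pd.read_csv(path, sep=delim, index_col=0)
        if df.shape[0] != df.shape[1]:
            raise ValueError(f"network matrix in {path} is not square")
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        missing = set(node_ids) - set(df.index)
        if missing or set(df.index) != set(node_ids):
            raise ValueError("matrix node ids do not match the feature table")
        df = df.reindex(index=node_ids, columns=node_ids)
        return NetworkMatrix(df.to_numpy(dtype=float), node_ids)

    if format != "edgelist":
        raise ValueError(f"unknown network format {format!r}")

    values = np.zeros((n, n), dtype=float)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter or "\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if delimiter is None and len(row) == 1:
                row = row[0].split()
            if len(row) not in (2, 3):
                raise ValueError(f"malformed edge row {row!r} in {path}")
            src, dst = row[0], row[1]
            w = float(row[2]) if len(row) == 3 else 1.0
            if src not in index or dst not in index:
                unknown = src if src not in index else dst
                raise ValueError(f"edge references unknown node {unknown!r}")
            i, j = index[src], index[dst]
            if sum_duplicates:
                values[i, j] += w
                if not directed and i != j:
                    values[j, i] += w
            else:
                values[i, j] = w
                if not directed:
                    values[j, i] = w
    return NetworkMatrix(values, node_ids)


def write_partition(
    partition: Partition, node_ids: Sequence[str], path: str | Path
) -> None:
    """Write a two-column TSV ``node_id <tab> label``, one row per node."""
    node_ids = [str(i) for i in node_ids]
    if len(node_ids) != partition.n_nodes:
        raise ValueError("node_ids length does not match partition")
    with open(path, "w", newline="") as fh:
        for nid, lab in zip(node_ids, partition.labels):
            fh.write(f"{nid}\t{int(lab)}\n")


def read_partition(
    path: str | Path, node_ids: Sequence[str] | None = None
) -> tuple[Partition, list[str]]:
    """Read a partition TSV; if ``node_ids`` is given, reorder to it."""
    ids: list[str] = []
    labels: list[int] = []
    with open(path, newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            nid, lab = line.split("\t")
            ids.append(nid)
            labels.append(int(lab))
    if node_ids is not None:
        node_ids = [str(i) for i in node_ids]
        lookup = dict(zip(ids, labels))
        if set(lookup) != set(node_ids):
            raise ValueError("partition node ids do not match")
        labels = [lookup[nid] for nid in node_ids]
        ids = list(node_ids)
    arr = np.asarray(labels, dtype=int)
    # labels need not be contiguous in a file; remap preserving first-seen order
    uniq = {lab: i for i, lab in enumerate(dict.fromkeys(sorted(set(labels))))}
    arr = np.asarray([uniq[l] for l in labels], dtype=int)
    return Partition(arr, k=len(uniq)), ids
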