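"""Partition-agreement metrics: contingency table, ARI, NMI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Partition


@dataclass
class ContingencyTable:
    """Co-occurrence counts n_kl = |S_k intersect T_l| with marginals."""

    counts: np.ndarray
    row_marginals: np.ndarray
    col_marginals: np.ndarray
    n: int


def _as_labels(p: Partition | np.ndarray) -> np.ndarray:
    if isinstance(p, Partition):
        return p.labels
    return np.asarray(p, dtype=int)


def contingency(S: Partition | np.ndarray, T: Partition | np.ndarray) -> ContingencyTable:
    """Exact K x L co-occurrence table of two partitions of the same nodes."""
    s = _as_labels(S)
    t = _as_labels(T)
    if s.size != t.size:
        raise ValueError("partitions must cover the same nodes")
    _, si = np.unique(s, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    k = si.max() + 1
    l = ti.max() + 1
    counts = np.zeros((k, l), dtype=np.int64)
    np.add.at(counts, (si, ti), 1)
    return ContingencyTable(
        counts=counts,
        row_marginals=counts.sum(axis=1),
        col_marginals=counts.sum(axis=0),
        n=int(s.size),
    )


def _choose2(x: np.ndarray) -> np.ndarray:
    x = x.astype(np.int64)
    return x * (x - 1) // 2


def adjusted_rand_index(S: Partition | np.ndarray, T: Partition | np.ndarray) -> float:
    """Hubert–Arabie adjusted Rand index.

    Chance-corrected pair-counting agreement computed from the contingency
    table: 1 iff the partitions coincide, 0 in expectation under random
    labellings with the same marginals (and exactly 0 against the trivial
    one-cluster partition).
    """
    table = contingency(S, T)
    if table.n < 2:
        raise ValueError("need at least 2 nodes")
    index = int(_choose2(table.counts).sum())
    sum_a = int(_choose2(table.row_marginals).sum())
    sum_b = int(_choose2(table.col_marginals).sum())
    pairs = table.n * (table.n - 1) // 2
    expected = sum_a * sum_b / pairs
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # both partitions trivial (all-singletons vs itself etc.)
        return 1.0
    return float((index - expected) / (maximum - expected))


def normalized_mutual_information(
    S: Partition | np.ndarray, T: Partition | np.ndarray
) -> float:
    """NMI with arithmetic-mean normalization, in [0, 1].

    MI(S,T) / ((H(S)+H(T))/2); equals 1 iff the partitions are identical
    up to relabeling.  If both entropies are zero the partitions are both
    trivial and hence identical, so 1 is returned.
    """
    table = contingency(S, T)
    n = table.n
    pkl = table.counts / n
    pk = table.row_marginals / n
    pl = table.col_marginals / n
    nz = table.counts > 0
    outer = np.outer(pk, pl)
    mi = float((pkl[nz] * np.log(pkl[nz] / outer[nz])).sum())
    hs = float(-(pk[pk > 0] * np.log(pk[pk > 0])).sum())
    ht = float(-(pl[pl > 0] * np.log(pl[pl > 0])).sum())
    denom = 0.5 * (hs + ht)
    if denom == 0.0:
        return 1.0
    return float(np.clip(mi / denom, 0.0, 1.0))
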