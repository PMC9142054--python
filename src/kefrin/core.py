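"""Extended K-means over the joint feature/network space.

The model approximates the feature table Y (N x V) and the link matrix P
(N x N) simultaneously by K communities, each carrying a two-fold center:
a feature-space vector c_k and a network-space vector of link intensities
lambda_k (one intensity per column of P — the nonsummability link model,
which makes network rows behave exactly like feature vectors).  The combined
least-squares criterion

    F(S, C, Lambda) = sum_k sum_{i in S_k} [ rho*d(y_i, c_k) + xi*d(p_i, lambda_k) ]

is minimized by alternating two steps, exactly as in batch K-means:

  1. assignment — each node goes to the community minimizing its combined
     distance (the Minimum Distance rule, ties to the smallest index);
  2. center update — each community's two centers become the within-cluster
     means of Y-rows and P-rows (re-normed to unit length under the cosine
     variant).

Three metrics d are supported: squared Euclidean (the least-squares case,
with guaranteed monotone criterion descent), Manhattan, and cosine distance
1 - cos(f, g).  For unit vectors the squared Euclidean distance equals twice
the cosine distance, which is why the cosine variant requires pre-normed
data rows; its center re-norming breaks least-squares optimality, so the
main loop additionally stops on a partition cycle.

Seeding follows a MaxMin (farthest-point) rule: the first seed is a random
node; each further seed is the node maximizing the sum of combined distances
to the seeds already chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import CommunityCenters, Partition
from .preprocess import row_norm

METRICS = ("euclidean", "manhattan", "cosine")


@dataclass
class KefrinConfig:
    """Algorithm settings.

    rho and xi weigh the feature and network spaces in the combined
    distance; both default to 1.  ``n_init`` random restarts are run and
    the one with the smallest final criterion is kept.  ``median_centers``
    switches the Manhattan variant to within-cluster medians (the true
    minimizer of the Manhattan criterion); the default reuses means, the
    plain algorithm with the metric substituted.
    """

    k: int
    metric: str = "euclidean"
    rho: float = 1.0
    xi: float = 1.0
    max_iter: int = 100
    n_init: int = 1
    rng_seed: int | None = None
    median_centers: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.rho < 0 or self.xi < 0 or self.rho + self.xi <= 0:
            raise ValueError("need rho >= 0, xi >= 0, rho + xi > 0")
        if self.max_iter < 1 or self.n_init < 1:
            raise ValueError("max_iter and n_init must be positive")


@dataclass
class FitResult:
    partition: Partition
    centers: CommunityCenters
    criterion_trajectory: list[float]
    n_iter: int
    converged: bool
    criterion: float
    seed_nodes: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def distance_matrix(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    """All pairwise distances between rows of X (n x d) and C (k x d)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if X.shape[1] != C.shape[1]:
        raise ValueError("dimension mismatch")
    if metric == "euclidean":
        xx = np.einsum("ij,ij->i", X, X)[:, None]
        cc = np.einsum("ij,ij->i", C, C)[None, :]
        return np.maximum(xx + cc - 2.0 * (X @ C.T), 0.0)
    if metric == "manhattan":
        return cdist(X, C, "cityblock")
    if metric == "cosine":
        # zero rows have cos = 0 by convention, hence distance 1
        return np.clip(1.0 - row_norm(X) @ row_norm(C).T, 0.0, 2.0)
    raise ValueError(f"unknown metric {metric!r}")


def pair_distance(x: np.ndarray, c: np.ndarray, metric: str) -> float:
    """Distance between two vectors: squared Euclidean, Manhattan or cosine."""
    x = np.asarray(x, dtype=float).ravel()
    c = np.asarray(c, dtype=float).ravel()
    if x.shape != c.shape:
        raise ValueError("length mismatch")
    return float(distance_matrix(x[None, :], c[None, :], metric)[0, 0])


def combined_distance_matrix(
    Y: np.ndarray, P: np.ndarray, centers: CommunityCenters, config: KefrinConfig
) -> np.ndarray:
    """N x K matrix of rho*d(y_i, c_k) + xi*d(p_i, lambda_k)."""
    D = np.zeros((Y.shape[0], centers.k))
    if config.rho != 0:
        D += config.rho * distance_matrix(Y, centers.C, config.metric)
    if config.xi != 0:
        D += config.xi * distance_matrix(P, centers.Lam, config.metric)
    return D


def combined_distance(
    i: int, k: int, Y: np.ndarray, P: np.ndarray, centers: CommunityCenters,
    config: KefrinConfig,
) -> float:
    """Combined distance of node i to community k's two-fold center."""
    d = config.rho * pair_distance(Y[i], centers.C[k], config.metric)
    d += config.xi * pair_distance(P[i], centers.Lam[k], config.metric)
    return float(d)


# ---------------------------------------------------------------------------
# alternating-minimization steps
# ---------------------------------------------------------------------------


def assign_clusters(
    Y: np.ndarray, P: np.ndarray, centers: CommunityCenters, config: KefrinConfig
) -> Partition:
    """Minimum Distance rule: each node to its nearest two-fold center.

    Ties break to the smallest cluster index.
    """
    D = combined_distance_matrix(Y, P, centers, config)
    return Partition(D.argmin(axis=1), k=centers.k)


def update_centers(
    Y: np.ndarray, P: np.ndarray, partition: Partition, config: KefrinConfig
) -> CommunityCenters:
    """Within-cluster means in both spaces (medians if configured for
    Manhattan); cosine centers are re-normed to unit length afterwards."""
    labels = partition.labels
    k = partition.k
    C = np.empty((k, Y.shape[1]))
    Lam = np.empty((k, P.shape[1]))
    use_median = config.median_centers and config.metric == "manhattan"
    for kk in range(k):
        mask = labels == kk
        if not mask.any():
            raise RuntimeError(f"empty cluster {kk} reached center update")
        if use_median:
            C[kk] = np.median(Y[mask], axis=0)
            Lam[kk] = np.median(P[mask], axis=0)
        else:
            C[kk] = Y[mask].mean(axis=0)
            Lam[kk] = P[mask].mean(axis=0)
    if config.metric == "cosine":
        C = row_norm(C)
        Lam = row_norm(Lam)
    return CommunityCenters(C, Lam)


def initialize_seeds(
    Y: np.ndarray,
    P: np.ndarray,
    config: KefrinConfig,
    rng: np.random.Generator,
) -> tuple[CommunityCenters, list[int]]:
    """MaxMin-style farthest-point seeding.

    The first seed is a uniformly random node; each subsequent seed is the
    not-yet-chosen node maximizing f(i) = sum over chosen seeds of the
    combined distance to that seed (ties to the smallest index).  Returns
    the seeded centers (copies of the seed nodes' Y and P rows) and the
    seed node indices.
    """
    n = Y.shape[0]
    if config.k > n:
        raise ValueError("more clusters than nodes")
    seeds = [int(rng.integers(n))]
    f = np.zeros(n)
    while len(seeds) < config.k:
        last = seeds[-1]
        d = config.rho * distance_matrix(Y, Y[[last]], config.metric)[:, 0]
        d += config.xi * distance_matrix(P, P[[last]], config.metric)[:, 0]
        f += d
        g = f.copy()
        g[seeds] = -np.inf
        seeds.append(int(np.argmax(g)))
    centers = CommunityCenters(Y[seeds].copy(), P[seeds].copy())
    return centers, seeds


def criterion_value(
    Y: np.ndarray,
    P: np.ndarray,
    partition: Partition,
    centers: CommunityCenters,
    config: KefrinConfig,
) -> float:
    """Combined criterion: each node's combined distance to its own centers."""
    total = 0.0
    for kk in range(partition.k):
        mask = partition.labels == kk
        if not mask.any():
            continue
        total += config.rho * distance_matrix(Y[mask], centers.C[[kk]], config.metric).sum()
        total += config.xi * distance_matrix(P[mask], centers.Lam[[kk]], config.metric).sum()
    return float(total)


def _repair_empty(
    labels: np.ndarray,
    centers: CommunityCenters,
    D: np.ndarray,
    Y: np.ndarray,
    P: np.ndarray,
    config: KefrinConfig,
) -> tuple[np.ndarray, CommunityCenters, np.ndarray]:
    """Reseed any emptied cluster from the node farthest from its center.

    Nodes that are the sole member of their cluster are not eligible, so a
    repair can never cascade into new empties.  The moved node's distance to
    its new center is 0, so the Euclidean criterion cannot increase.
    """
    counts = np.bincount(labels, minlength=config.k)
    if (counts > 0).all():
        return labels, centers, D
    labels = labels.copy()
    centers = centers.copy()
    for kk in np.flatnonzero(counts == 0):
        sizes = np.bincount(labels, minlength=config.k)
        eligible = sizes[labels] > 1
        if not eligible.any():  # k == n edge case
            continue
        col = np.where(eligible, D[:, kk], -np.inf)
        i = int(np.argmax(col))
        centers.C[kk] = Y[i]
        centers.Lam[kk] = P[i]
        labels[i] = kk
        D[:, kk] = config.rho * distance_matrix(Y, centers.C[[kk]], config.metric)[:, 0]
        D[:, kk] += config.xi * distance_matrix(P, centers.Lam[[kk]], config.metric)[:, 0]
    return labels, centers, D


def _fit_once(
    Y: np.ndarray, P: np.ndarray, config: KefrinConfig, rng: np.random.Generator
) -> FitResult:
    n = Y.shape[0]
    centers, seeds = initialize_seeds(Y, P, config, rng)
    trajectory: list[float] = []
    prev: np.ndarray | None = None
    seen: set[bytes] = set()
    converged = False
    labels = np.zeros(n, dtype=int)
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        D = combined_distance_matrix(Y, P, centers, config)
        labels = D.argmin(axis=1)
        labels, centers, D = _repair_empty(labels, centers, D, Y, P, config)
        trajectory.append(float(D[np.arange(n), labels].sum()))
        if prev is not None and np.array_equal(labels, prev):
            converged = True
            break
        key = labels.tobytes()
        if key in seen:
            # partition cycle (possible under cosine re-norming): stop
            break
        seen.add(key)
        partition = Partition(labels, k=config.k)
        centers = update_centers(Y, P, partition, config)
        prev = labels

    partition = Partition(labels, k=config.k)
    final_centers = update_centers(Y, P, partition, config)
    final = criterion_value(Y, P, partition, final_centers, config)
    return FitResult(
        partition=partition,
        centers=final_centers,
        criterion_trajectory=trajectory,
        n_iter=n_iter,
        converged=converged,
        criterion=final,
        seed_nodes=seeds,
    )


def fit(Y: np.ndarray, P: np.ndarray, config: KefrinConfig) -> FitResult:
    """Run the full algorithm with ``n_init`` restarts; keep the best run.

    Y and P must already be standardized as desired; under the cosine
    metric their rows must be pre-normed.  Raises if K exceeds the number
    of distinct node profiles, since K distinct seeds are then impossible.
    """
    Y = np.asarray(Y, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y.shape[0] != P.shape[0]:
        raise ValueError("Y and P disagree on the number of nodes")
    if config.k > Y.shape[0]:
        raise ValueError("more clusters than nodes")
    profiles = np.unique(np.hstack([Y, P]), axis=0)
    if profiles.shape[0] < config.k:
        raise ValueError("fewer distinct node profiles than clusters")

    rng = np.random.default_rng(config.rng_seed)
    best: FitResult | None = None
    for _ in range(config.n_init):
        result = _fit_once(Y, P, config, rng)
        if best is None or result.criterion < best.criterion:
            best = result
    assert best is not None
    return best
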