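"""Planted-partition generator for feature-rich networks.

Emulates the benchmark design used throughout the synthetic experiments:

* **Network** — community sizes are drawn at random subject to a minimum
  size and to summing to N; every within-community node pair receives an
  edge with probability p, every between-community pair with probability q
  (a planted-partition graph, symmetric, zero diagonal).
* **Quantitative features** — each community is a spherical-ish Gaussian:
  center components are Uniform(-alpha, +alpha) and the diagonal covariance
  entries are Uniform(0.05, 0.1).  The spread factor alpha in (0, 1]
  controls cluster intermix: the smaller alpha, the closer the centers and
  the heavier the overlap.
* **Categorical features** — each feature v has L_v categories, L_v drawn
  from {2, ..., L_max}; each community has a planted center of categories
  (no two centers may coincide at more than 50% of the features).  An entry
  copies its community's center with probability epsilon and is otherwise
  uniformly random over the feature's categories, so the per-entry match
  probability is epsilon + (1 - epsilon)/L_v.  Larger epsilon means more
  homogeneous communities.
* **Noise features** — optionally, ceil(V/2) extra columns of uniform noise
  over the global [min, max] of the original quantitative data are appended
  (half the original data replicated as noise).
* **Mixed data** — equal numbers of quantitative and categorical features.

Two canonical problem sizes are used by the benchmark harness: small
(N=200, K=5, 5 features per type, L_max=10) and medium (N=1000, K=10,
10 features per type, L_max=15).  K and the feature counts are generator
defaults of this package (configurable); the minimum community size is 30
so that the edge probabilities are meaningful within every block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import (
    CATEGORICAL,
    QUANTITATIVE,
    FeatureMatrix,
    NetworkMatrix,
    Partition,
)

_SIZE_TRIES = 100_000
_CENTER_TRIES = 10_000


@dataclass
class GeneratorConfig:
    """Settings of the planted-partition benchmark generator."""

    n: int = 200
    k: int = 5
    p: float = 0.9
    q: float = 0.3
    alpha: float = 0.9
    epsilon: float = 0.9
    l_max: int = 10
    v_quant: int = 5
    v_cat: int = 5
    noise: bool = False
    min_size: int = 30
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.n < 2:
            raise ValueError("need n >= 2 and k >= 1")
        if self.k * self.min_size > self.n:
            raise ValueError("k * min_size exceeds n: no feasible community sizes")
        if not (0.0 <= self.q <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError("p and q must lie in [0, 1]")
        if self.q > self.p:
            raise ValueError("require q <= p (assortative planted partition)")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if self.l_max < 2:
            raise ValueError("l_max must be >= 2")


@dataclass
class SyntheticDataset:
    """A generated feature-rich network with its planted ground truth."""

    features: FeatureMatrix
    network: NetworkMatrix
    truth: Partition
    config: GeneratorConfig
    flavor: str

    def config_echo(self) -> dict:
        echo = asdict(self.config)
        echo["flavor"] = self.flavor
        return echo


def draw_community_sizes(
    n: int, k: int, min_size: int, rng: np.random.Generator
) -> list[int]:
    """Random community cardinalities: each >= min_size, summing to n.

    Draws k-1 uniform cut points of the index range and rejects until the
    minimum-size constraint holds (a capped rejection loop).
    """
    if k * min_size > n:
        raise ValueError("k * min_size exceeds n: infeasible")
    if k == 1:
        return [n]
    for _ in range(_SIZE_TRIES):
        cuts = np.sort(rng.integers(0, n + 1, size=k - 1))
        sizes = np.diff(np.concatenate([[0], cuts, [n]]))
        if (sizes >= min_size).all():
            return [int(s) for s in sizes]
    raise RuntimeError("could not draw community sizes within the retry cap")


def _labels_from_sizes(sizes: list[int]) -> np.ndarray:
    return np.repeat(np.arange(len(sizes)), sizes)


def generate_network(
    sizes: list[int], p: float, q: float, rng: np.random.Generator
) -> np.ndarray:
    """Planted-partition adjacency: within-pair edges Bernoulli(p),
    between-pair Bernoulli(q); symmetric 0/1 with zero diagonal."""
    labels = _labels_from_sizes(sizes)
    n = labels.size
    same = labels[:, None] == labels[None, :]
    prob = np.where(same, p, q)
    draws = rng.random((n, n))
    upper = np.triu(draws < prob, k=1)
    adj = (upper | upper.T).astype(float)
    return adj


def generate_quantitative(
    sizes: list[int], alpha: float, v_quant: int, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian cluster features: centers Uniform(-alpha, alpha) per
    component, diagonal variances Uniform(0.05, 0.1) per component."""
    if v_quant < 1:
        raise ValueError("v_quant must be >= 1")
    k = len(sizes)
    centers = rng.uniform(-alpha, alpha, size=(k, v_quant))
    variances = rng.uniform(0.05, 0.1, size=(k, v_quant))
    blocks = [
        centers[kk] + np.sqrt(variances[kk]) * rng.standard_normal((sz, v_quant))
        for kk, sz in enumerate(sizes)
    ]
    return np.vstack(blocks)


def add_noise_features(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Append ceil(V/2) i.i.d. uniform noise columns spanning the global
    [min, max] of the original data."""
    X = np.asarray(X, dtype=float)
    m = math.ceil(X.shape[1] / 2)
    lo, hi = X.min(), X.max()
    noise = rng.uniform(lo, hi, size=(X.shape[0], m))
    return np.hstack([X, noise])


def _categorical_centers(
    k: int, levels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Planted category centers; no two may agree on more than 50% of
    features.  Whole-matrix rejection with a retry cap."""
    v = levels.size
    for _ in range(_CENTER_TRIES):
        centers = np.column_stack([rng.integers(0, L, size=k) for L in levels])
        ok = True
        for a in range(k):
            for b in range(a + 1, k):
                if (centers[a] == centers[b]).sum() > 0.5 * v:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return centers
    raise RuntimeError("could not place distinct categorical centers within the retry cap")


def generate_categorical(
    sizes: list[int],
    epsilon: float,
    v_cat: int,
    l_max: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Categorical label matrix (integer codes) with planted centers.

    Each entry copies its community center with probability epsilon and is
    otherwise uniform over that feature's categories.
    """
    if v_cat < 1:
        raise ValueError("v_cat must be >= 1")
    levels = rng.integers(2, l_max + 1, size=v_cat)
    centers = _categorical_centers(len(sizes), levels, rng)
    labels = _labels_from_sizes(sizes)
    n = labels.size
    X = centers[labels].copy()
    randomize = rng.random((n, v_cat)) >= epsilon
    for j, L in enumerate(levels):
        col = randomize[:, j]
        X[col, j] = rng.integers(0, L, size=int(col.sum()))
    return X


def _feature_matrix(
    quant: np.ndarray | None,
    cat: np.ndarray | None,
    node_ids: list[str],
) -> FeatureMatrix:
    columns: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    if quant is not None:
        for j in range(quant.shape[1]):
            columns.append(quant[:, j])
            names.append(f"q{j}")
            kinds.append(QUANTITATIVE)
    if cat is not None:
        for j in range(cat.shape[1]):
            columns.append(np.array([f"c{int(x)}" for x in cat[:, j]], dtype=object))
            names.append(f"x{j}")
            kinds.append(CATEGORICAL)
    dtype = object if cat is not None else float
    values = np.column_stack(columns).astype(dtype)
    return FeatureMatrix(values, node_ids, names, kinds)


def generate(config: GeneratorConfig, flavor: str = "quantitative") -> SyntheticDataset:
    """Generate a full dataset: network + features + planted partition.

    ``flavor`` is ``quantitative``, ``categorical`` or ``mixed``; noise
    features (if enabled) are derived from the quantitative block.
    """
    if flavor not in ("quantitative", "categorical", "mixed"):
        raise ValueError(f"unknown flavor {flavor!r}")
    rng = np.random.default_rng(config.rng_seed)
    sizes = draw_community_sizes(config.n, config.k, config.min_size, rng)
    adj = generate_network(sizes, config.p, config.q, rng)

    quant = None
    cat = None
    if flavor in ("quantitative", "mixed"):
        quant = generate_quantitative(sizes, config.alpha, config.v_quant, rng)
        if config.noise:
            quant = add_noise_features(quant, rng)
    elif config.noise:
        raise ValueError("noise features require quantitative features")
    if flavor in ("categorical", "mixed"):
        if flavor == "mixed" and config.v_quant != config.v_cat:
            raise ValueError("mixed data requires v_quant == v_cat")
        cat = generate_categorical(sizes, config.epsilon, config.v_cat, config.l_max, rng)

    width = len(str(config.n))
    node_ids = [f"n{i:0{width}d}" for i in range(config.n)]
    features = _feature_matrix(quant, cat, node_ids)
    network = NetworkMatrix(adj, node_ids)
    truth = Partition(_labels_from_sizes(sizes), k=config.k)
    return SyntheticDataset(features, network, truth, config, flavor)


def generate_mixed(config: GeneratorConfig) -> SyntheticDataset:
    """Equal numbers of quantitative and categorical features plus network."""
    return generate(config, flavor="mixed")


def size_defaults(size: str) -> dict:
    """Canonical small/medium problem sizes used by the benchmark harness."""
    if size == "small":
        return dict(n=200, k=5, v_quant=5, v_cat=5, l_max=10)
    if size == "medium":
        return dict(n=1000, k=10, v_quant=10, v_cat=10, l_max=15)
    raise ValueError(f"unknown size {size!r}")
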