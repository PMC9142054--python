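"""Model/Results interface over the extended K-means core.

``KefrinModel`` holds the data (feature table + link matrix, reindexed to a
single node order) together with the clustering settings, applies the
configured standardization once at construction, and ``fit`` runs the
alternating minimization with random restarts.  ``KefrinResults`` carries
the partition, the two-fold centers, the criterion trajectory and
convergence diagnostics, and offers ``summary()``, scoring against a ground
truth, and partition export.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .data import (
    QUANTITATIVE,
    CATEGORICAL,
    FeatureMatrix,
    NetworkMatrix,
    Partition,
    read_features,
    read_network,
    write_partition,
)
from .metrics import adjusted_rand_index, normalized_mutual_information
from .preprocess import standardize


def _coerce_features(features) -> FeatureMatrix:
    if isinstance(features, FeatureMatrix):
        return features
    if isinstance(features, pd.DataFrame):
        kinds = [
            QUANTITATIVE if pd.api.types.is_numeric_dtype(features[c]) else CATEGORICAL
            for c in features.columns
        ]
        dtype = float if all(k == QUANTITATIVE for k in kinds) else object
        return FeatureMatrix(
            features.to_numpy().astype(dtype),
            [str(i) for i in features.index],
            [str(c) for c in features.columns],
            kinds,
        )
    arr = np.asarray(features, dtype=float)
    ids = [str(i) for i in range(arr.shape[0])]
    names = [f"f{j}" for j in range(arr.shape[1])]
    return FeatureMatrix(arr, ids, names, [QUANTITATIVE] * arr.shape[1])


def _coerce_network(network, node_ids: list[str]) -> NetworkMatrix:
    if isinstance(network, NetworkMatrix):
        nm = network
    elif isinstance(network, pd.DataFrame):
        nm = NetworkMatrix(network.to_numpy(dtype=float), [str(i) for i in network.index])
    else:
        nm = NetworkMatrix(np.asarray(network, dtype=float), list(node_ids))
    if list(nm.node_ids) != list(node_ids):
        if set(nm.node_ids) != set(node_ids):
            raise ValueError("network nodes do not match the feature table")
        order = [nm.node_ids.index(i) for i in node_ids]
        nm = NetworkMatrix(nm.values[np.ix_(order, order)], list(node_ids))
    return nm


class KefrinModel:
    """Extended K-means for a feature-rich network.

    Parameters
    ----------
    features, network
        Node-by-feature table and node-by-node link matrix (FeatureMatrix /
        NetworkMatrix, DataFrame, or plain arrays).  The network is
        reindexed to the feature table's node order.
    k
        Number of communities (>= 2 for a meaningful fit).
    metric
        ``euclidean`` (squared Euclidean; least-squares case), ``manhattan``
        or ``cosine``.
    rho, xi
        Nonnegative weights of the feature and network spaces.
    feature_std, network_std
        Standardization options (see :mod:`kefrin.preprocess`);
        ``network_std='auto'`` selects the modularity shift for purely
        quantitative data and the scale shift when categorical features are
        present.  The cosine metric additionally row-norms both matrices.
    """

    def __init__(
        self,
        features,
        network,
        k: int,
        metric: str = "euclidean",
        rho: float = 1.0,
        xi: float = 1.0,
        feature_std: str = "z",
        network_std: str = "auto",
        median_centers: bool = False,
    ) -> None:
        self.features = _coerce_features(features)
        self.network = _coerce_network(network, self.features.node_ids)
        self.k = int(k)
        self.metric = metric
        self.rho = float(rho)
        self.xi = float(xi)
        self.feature_std = feature_std
        self.network_std = network_std
        self.median_centers = bool(median_centers)
        self.exog_features, self.exog_network = standardize(
            self.features, self.network, feature_std, network_std, metric
        )

    @classmethod
    def from_files(
        cls,
        features_path: str | Path,
        network_path: str | Path,
        k: int,
        network_format: str = "edgelist",
        directed: bool = False,
        delimiter: str | None = None,
        **kwargs,
    ) -> "KefrinModel":
        features = read_features(features_path, delimiter=delimiter)
        network = read_network(
            network_path,
            features.node_ids,
            format=network_format,
            directed=directed,
        )
        return cls(features, network, k, **kwargs)

    @classmethod
    def from_dataframes(
        cls, features: pd.DataFrame, network: pd.DataFrame, k: int, **kwargs
    ) -> "KefrinModel":
        return cls(features, network, k, **kwargs)

    @property
    def node_ids(self) -> list[str]:
        return self.features.node_ids

    def _config(self, n_init: int, max_iter: int, seed: int | None) -> core.KefrinConfig:
        return core.KefrinConfig(
            k=self.k,
            metric=self.metric,
            rho=self.rho,
            xi=self.xi,
            max_iter=max_iter,
            n_init=n_init,
            rng_seed=seed,
            median_centers=self.median_centers,
        )

    def fit(
        self, n_init: int = 10, max_iter: int = 100, seed: int | None = None
    ) -> "KefrinResults":
        config = self._config(n_init, max_iter, seed)
        result = core.fit(self.exog_features, self.exog_network, config)
        return KefrinResults(self, config, result)


class KefrinResults:
    """Fit results: partition, two-fold centers, diagnostics."""

    def __init__(
        self, model: KefrinModel, config: core.KefrinConfig, result: core.FitResult
    ) -> None:
        self.model = model
        self.config = config
        self._result = result

    @property
    def partition(self) -> Partition:
        return self._result.partition

    @property
    def labels(self) -> np.ndarray:
        return self._result.partition.labels

    @property
    def centers(self):
        return self._result.centers

    @property
    def criterion(self) -> float:
        return self._result.criterion

    @property
    def criterion_path(self) -> list[float]:
        return self._result.criterion_trajectory

    @property
    def n_iter(self) -> int:
        return self._result.n_iter

    @property
    def converged(self) -> bool:
        return self._result.converged

    @property
    def seed_nodes(self) -> list[int]:
        return self._result.seed_nodes

    def cluster_sizes(self) -> np.ndarray:
        return self.partition.sizes()

    def score(self, truth: Partition | np.ndarray | Sequence[int]) -> dict:
        """ARI and NMI of the fitted partition against a reference one."""
        truth = np.asarray(truth.labels if isinstance(truth, Partition) else truth)
        return {
            "ari": adjusted_rand_index(self.labels, truth),
            "nmi": normalized_mutual_information(self.labels, truth),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.model.node_ids, "cluster": self.labels}
        ).set_index("node_id")

    def save_partition(self, path: str | Path) -> None:
        write_partition(self.partition, self.model.node_ids, path)

    def report(self) -> dict:
        """JSON-serializable run report (enough to reproduce the run)."""
        return {
            "k": self.config.k,
            "metric": self.config.metric,
            "rho": self.config.rho,
            "xi": self.config.xi,
            "n_init": self.config.n_init,
            "max_iter": self.config.max_iter,
            "seed": self.config.rng_seed,
            "feature_std": self.model.feature_std,
            "network_std": self.model.network_std,
            "n_nodes": len(self.model.node_ids),
            "criterion": self.criterion,
            "criterion_trajectory": [float(v) for v in self.criterion_path],
            "n_iter": self.n_iter,
            "converged": self.converged,
            "seed_nodes": [int(i) for i in self.seed_nodes],
            "cluster_sizes": [int(s) for s in self.cluster_sizes()],
        }

    def summary(self) -> str:
        sizes = ", ".join(str(int(s)) for s in self.cluster_sizes())
        lines = [
            "Extended K-means (feature-rich network) results",
            "=" * 47,
            f"nodes:             {len(self.model.node_ids)}",
            f"features (design): {self.model.exog_features.shape[1]}",
            f"communities (K):   {self.config.k}",
            f"metric:            {self.config.metric}",
            f"rho / xi:          {self.config.rho:g} / {self.config.xi:g}",
            f"criterion:         {self.criterion:.6g}",
            f"iterations:        {self.n_iter} (converged: {self.converged})",
            f"restarts:          {self.config.n_init}",
            f"cluster sizes:     {sizes}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<KefrinResults k={self.config.k} metric={self.config.metric!r} "
            f"criterion={self.criterion:.4g} converged={self.converged}>"
        )
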