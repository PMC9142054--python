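"""Standardization operators for features and link matrices.

Feature options: (Z) z-scoring with the population standard deviation,
(R) range standardization (center by mean, divide by max - min).  Network
options: (M) modularity shift — subtract the degree-product null expectation
p_i+ p_+j / p_++ from every entry, (S) scale shift — subtract the grand mean
link weight.  Categorical columns are one-hot encoded before any scaling so
the dummies are treated as ordinary numeric columns.  The cosine variant of
the clustering additionally requires every data row to be unit-normed, which
``row_norm`` provides (all-zero rows are left zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CATEGORICAL, QUANTITATIVE, FeatureMatrix, NetworkMatrix


def _as_float(Y: FeatureMatrix) -> np.ndarray:
    if Y.values.dtype.kind == "O":
        raise ValueError("categorical columns must be one-hot encoded first")
    return np.asarray(Y.values, dtype=float)


def zscore_features(Y: FeatureMatrix) -> FeatureMatrix:
    """Center each column by its mean and divide by its population sd."""
    values = _as_float(Y)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population form (ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant feature column(s): {[Y.feature_names[i] for i in bad]}")
    return FeatureMatrix(
        (values - mean) / sd, list(Y.node_ids), list(Y.feature_names), list(Y.feature_kinds)
    )


def range_features(Y: FeatureMatrix) -> FeatureMatrix:
    """Center each column by its mean and divide by its range (max - min)."""
    values = _as_float(Y)
    mean = values.mean(axis=0)
    rng = values.max(axis=0) - values.min(axis=0)
    bad = np.flatnonzero(rng == 0)
    if bad.size:
        raise ValueError(f"constant feature column(s): {[Y.feature_names[i] for i in bad]}")
    return FeatureMatrix(
        (values - mean) / rng, list(Y.node_ids), list(Y.feature_names), list(Y.feature_kinds)
    )


def modularity_shift_network(P: NetworkMatrix) -> NetworkMatrix:
    """Subtract the random-interaction score r_ij = p_i+ p_+j / p_++.

    This clears link weights of what a degree-preserving null model would
    produce; every row sum and column sum of the result is zero.
    """
    values = np.asarray(P.values, dtype=float)
    total = values.sum()
    if total == 0:
        raise ValueError("modularity shift undefined for an all-zero network")
    row = values.sum(axis=1, keepdims=True)
    col = values.sum(axis=0, keepdims=True)
    return NetworkMatrix(values - row * col / total, list(P.node_ids))


def scale_shift_network(P: NetworkMatrix) -> NetworkMatrix:
    """Subtract the mean link score pi = sum_ij p_ij / N^2 from every entry."""
    values = np.asarray(P.values, dtype=float)
    return NetworkMatrix(values - values.mean(), list(P.node_ids))


def one_hot_encode(Y: FeatureMatrix) -> FeatureMatrix:
    """Expand each categorical column into 0/1 dummies, one per observed level.

    Quantitative columns pass through unchanged; dummy columns are named
    ``name=level`` and keep the categorical kind tag.
    """
    if not Y.has_categorical:
        return Y
    columns: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    for j, (name, kind) in enumerate(zip(Y.feature_names, Y.feature_kinds)):
        col = Y.values[:, j]
        if kind == QUANTITATIVE:
            columns.append(np.asarray(col, dtype=float))
            names.append(name)
            kinds.append(QUANTITATIVE)
        else:
            dummies = pd.get_dummies(pd.Series(col).astype(str))
            for level in dummies.columns:
                columns.append(dummies[level].to_numpy(dtype=float))
                names.append(f"{name}={level}")
                kinds.append(CATEGORICAL)
    return FeatureMatrix(np.column_stack(columns), list(Y.node_ids), names, kinds)


def row_norm(M: np.ndarray) -> np.ndarray:
    """Divide every nonzero row by its Euclidean norm; zero rows stay zero."""
    M = np.asarray(M, dtype=float)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    safe = np.where(norms == 0, 1.0, norms)
    return M / safe


def standardize(
    Y: FeatureMatrix,
    P: NetworkMatrix,
    feature_std: str = "z",
    network_std: str = "auto",
    metric: str = "euclidean",
) -> tuple[np.ndarray, np.ndarray]:
    """Default preprocessing pipeline, returning plain (Y, P) float arrays.

    Features: one-hot encode, then ``z``, ``range`` or ``none``.  Network:
    ``modularity``, ``shift`` or ``none``; ``auto`` selects the modularity
    shift for purely quantitative data and the scale shift whenever any
    categorical feature is present.  For the cosine metric both matrices are
    row-normed afterwards, as that variant requires unit data vectors.
    """
    had_categorical = Y.has_categorical
    Y = one_hot_encode(Y)

    if feature_std == "z":
        Y = zscore_features(Y)
    elif feature_std == "range":
        Y = range_features(Y)
    elif feature_std != "none":
        raise ValueError(f"unknown feature_std {feature_std!r}")

    if network_std == "auto":
        network_std = "shift" if had_categorical else "modularity"
    if network_std == "modularity":
        P = modularity_shift_network(P)
    elif network_std == "shift":
        P = scale_shift_network(P)
    elif network_std != "none":
        raise ValueError(f"unknown network_std {network_std!r}")

    Ym = np.asarray(Y.values, dtype=float)
    Pm = np.asarray(P.values, dtype=float)
    if metric == "cosine":
        Ym = row_norm(Ym)
        Pm = row_norm(Pm)
    return Ym, Pm
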