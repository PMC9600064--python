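"""Multiclass ReliefF feature weighting.

Exhaustive ReliefF (every observation serves as a reference instance, no
sampling) with ``k`` nearest hits and, for each contrast class, ``k``
nearest misses found under the Manhattan distance.  Miss contributions are
weighted by the class prior divided by ``1 - P(class of the reference)``;
per-feature differences are normalized by the feature range so every
feature contributes on the same scale.  With no sampling the weights are
fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidInputError

__all__ = ["relieff_weights"]


def relieff_weights(matrix, labels, n_neighbors: int = 10) -> np.ndarray:
    """One ReliefF weight per feature column.

    Parameters
    ----------
    matrix : (n_obs, n_features) array
    labels : length-n_obs sequence of class labels
    n_neighbors : nearest hits/misses per reference instance; clamped per
        class to the available neighbor count.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("matrix must be 2-D with one label per row")
    n, d = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise InvalidInputError(
            f"ReliefF needs >= 2 members per class; class {small!r} has {counts.min()}"
        )
    priors = dict(zip(classes, counts / n))

    rng_feat = X.max(axis=0) - X.min(axis=0)
    rng_feat[rng_feat == 0.0] = 1.0  # constant features: diffs are 0 anyway

    D = cdist(X, X, metric="cityblock")
    np.fill_diagonal(D, np.inf)
    class_rows = {c: np.flatnonzero(y == c) for c in classes}

    W = np.zeros(d)
    for i in range(n):
        ci = y[i]
        hits = class_rows[ci]
        hits = hits[hits != i]
        k_h = min(n_neighbors, hits.size)
        nearest_h = hits[np.argsort(D[i, hits], kind="stable")[:k_h]]
        W -= np.abs(X[nearest_h] - X[i]).sum(axis=0) / (rng_feat * n * k_h)
        miss_norm = 1.0 - priors[ci]
        for c in classes:
            if c == ci:
                continue
            rows = class_rows[c]
            k_m = min(n_neighbors, rows.size)
            nearest_m = rows[np.argsort(D[i, rows], kind="stable")[:k_m]]
            w_c = priors[c] / miss_norm
            W += w_c * np.abs(X[nearest_m] - X[i]).sum(axis=0) / (rng_feat * n * k_m)
    return W
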