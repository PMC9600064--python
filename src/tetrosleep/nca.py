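"""Diagonal neighborhood component analysis for feature weighting.

Learns one nonnegative relevance weight per feature by maximizing the
expected leave-one-out soft-neighbor classification accuracy

    F(w) = sum_i sum_{j != i, y_j = y_i} p_ij  -  lambda * sum_r w_r^2,
    p_ij = exp(-D_ij) / sum_{k != i} exp(-D_ik),
    D_ij = sum_r w_r^2 |x_ir - x_jr|,

i.e. a weighted Manhattan metric whose squared weights act as per-feature
scales.  This is the feature-selection flavor of NCA (a diagonal metric,
not the full linear transform): after optimization ``w_r^2`` ranks
features by how much they help nearest-neighbor class discrimination.

The optimization is deterministic: weights start uniform, scaled so the
mean pairwise distance is 1 (a saturated softmax at the start has a
vanishing gradient, which would leave L-BFGS steered by the regularizer
alone), and L-BFGS runs to a fixed gradient tolerance.  Regularization
defaults to ``1/n_obs``, which drives irrelevant-feature weights toward 0.

The gradient is assembled in row chunks so the ``n x n x d`` absolute
difference tensor never materializes at once; chunk tensors use float32 to
halve memory traffic (sums are accumulated in float64).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .errors import InvalidInputError

__all__ = ["nca_weights"]

# target elements per chunk tensor (~100 MB of float32)
_CHUNK_BUDGET = 25_000_000


def _objective(w, X32, same, lam, chunk):
    n, d = X32.shape
    w2 = (w * w).astype(np.float32)
    f = 0.0
    grad_core = np.zeros(d)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        T = np.abs(X32[start:stop, None, :] - X32[None, :, :])  # (c, n, d)
        Dblk = T @ w2  # (c, n)
        for local, i in enumerate(range(start, stop)):
            Dblk[local, i] = np.inf
        Dblk -= Dblk.min(axis=1, keepdims=True)
        P = np.exp(-Dblk.astype(np.float64))
        P /= P.sum(axis=1, keepdims=True)
        p_in = (P * same[start:stop]).sum(axis=1)  # prob of a same-class neighbor
        f += p_in.sum()
        # dF/dw_r = -2 w_r [ sum_i sum_j B_ij |x_ir - x_jr| ] - 2 lam w_r
        B = same[start:stop] * P - p_in[:, None] * P
        grad_core += np.einsum("cn,cnd->d", B.astype(np.float32), T, dtype=np.float64)
    fval = f - lam * float(w @ w)
    grad = -2.0 * w * grad_core - 2.0 * lam * w
    return -fval, -grad


def _uniform_scale(X: np.ndarray) -> float:
    """Uniform start weight putting the mean pairwise distance near 1.

    The mean pairwise |x_i - x_j| of one feature equals
    ``(2 / (n(n-1))) * sum_i (2i - n + 1) x_(i)`` over the sorted values;
    summing over features gives the mean unweighted Manhattan distance D0,
    and ``w = 1/sqrt(D0)`` rescales it to 1.
    """
    n = X.shape[0]
    ranks = 2.0 * np.arange(n) - (n - 1)
    mean_dist = float((np.sort(X, axis=0) * ranks[:, None]).sum() * 2.0 / (n * (n - 1)))
    return 1.0 / np.sqrt(max(mean_dist, np.finfo(float).tiny))


def nca_weights(
    matrix,
    labels,
    reg: float | None = None,
    gtol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Per-feature NCA relevance weights (the learned ``w``, all finite).

    Parameters
    ----------
    matrix : (n_obs, n_features) array, ideally scaled to a common range
    labels : class label per row (>= 2 classes)
    reg : L2 regularization strength lambda; default ``1/n_obs``
    gtol : L-BFGS projected-gradient tolerance
    max_iter : L-BFGS iteration cap
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("matrix must be 2-D with one label per row")
    n, d = X.shape
    if n < 3 or np.unique(y).size < 2:
        raise InvalidInputError("NCA needs >= 3 observations in >= 2 classes")
    lam = (1.0 / n) if reg is None else float(reg)
    same = (y[:, None] == y[None, :]) & ~np.eye(n, dtype=bool)
    chunk = max(1, min(n, _CHUNK_BUDGET // max(1, n * d)))
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    res = minimize(
        _objective,
        x0=np.full(d, _uniform_scale(X)),
        args=(X32, same.astype(np.float32), lam, chunk),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol},
    )
    return np.asarray(res.x)
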