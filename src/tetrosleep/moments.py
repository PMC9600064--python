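"""The 18 statistical moments applied to signals and textural vectors.

The moment list mixes linear summaries (mean, extremes, median, variance,
energy) with entropy-type nonlinear features computed on the normalized
energy distribution ``p_j = x_j^2 / sum(x^2)``.  Entries 13–15 duplicate
earlier entries; the duplicates are kept so the vector length stays 18 and
downstream indexing is stable.  Conventions: natural logarithm,
``0·log 0 = 0``, and an all-zero input yields 0 for every entropy entry.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = ["compute_moments", "N_MOMENTS"]

N_MOMENTS = 18


def _energy_distribution(x: np.ndarray) -> np.ndarray:
    e = x * x
    total = e.sum()
    if total <= 0.0:
        return np.zeros_like(e)
    return e / total


def compute_moments(vector) -> np.ndarray:
    """18 statistical moments of a 1-D vector, in canonical order.

    1. mean
    2. sum of absolute deviations / (n - 1)
    3. max
    4. min
    5. median
    6. population variance
    7. mean of squares
    8. mean absolute deviation
    9. range (max - min)
    10. max - median
    11. mean absolute value
    12. log-energy entropy  -sum log(p_j^2)   (zero terms skipped)
    13. range (duplicate of 9)
    14. min (duplicate of 4)
    15. duplicate of 2
    16. Shannon entropy  -sum p_j log p_j
    17. energy  sum x^2
    18. -sum p_j^2 log p_j^2

    where ``p_j = x_j^2 / sum x^2``.
    """
    x = np.asarray(vector, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError(f"moments need a 1-D vector of length >= 2, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("moments input contains non-finite values")

    n = x.size
    mean = x.mean()
    dev = np.abs(x - mean)
    xmax, xmin = x.max(), x.min()
    med = float(np.median(x))
    p = _energy_distribution(x)
    pos = p > 0.0
    log_p = np.log(p[pos])
    p2 = p[pos] ** 2

    m = np.empty(N_MOMENTS)
    m[0] = mean
    m[1] = dev.sum() / (n - 1)
    m[2] = xmax
    m[3] = xmin
    m[4] = med
    m[5] = ((x - mean) ** 2).mean()
    m[6] = (x * x).mean()
    m[7] = dev.mean()
    m[8] = xmax - xmin
    m[9] = xmax - med
    m[10] = np.abs(x).mean()
    m[11] = -2.0 * log_p.sum()            # -sum log(p^2)
    m[12] = xmax - xmin
    m[13] = xmin
    m[14] = m[1]
    m[15] = -(p[pos] * log_p).sum()
    m[16] = (x * x).sum()
    m[17] = -(p2 * 2.0 * log_p).sum()     # -sum p^2 log(p^2)
    return m
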