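"""Non-overlapping pairwise pooling operators.

Four pooling statistics over adjacent sample pairs drive the multilevel
decomposition: maximum pooling (the level-update operator) and the triple
of average, absolute-average and absolute-maximum pooling (the per-level
decomposers M1, M2, M3).  All operators halve the signal; a trailing
unpaired sample of an odd-length signal is discarded rather than padded,
so pooled histograms never see artificial amplitudes.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import InvalidInputError

__all__ = ["PooledTriple", "max_pool", "decompose_triple"]


class PooledTriple(NamedTuple):
    """The three per-level decomposed signals.

    m1 : average pooled signal (pair means)
    m2 : absolute-average pooled signal, ``|pair mean|``
    m3 : absolute-maximum pooled signal, ``max(|x_i|, |x_{i+1}|)``
    """

    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray


def _as_pairs(signal) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError(f"expected a 1-D signal, got shape {x.shape}")
    if x.size < 2:
        raise InvalidInputError(f"pooling needs at least 2 samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("signal contains non-finite values")
    n = x.size // 2
    return x[: 2 * n].reshape(n, 2)


def max_pool(signal) -> np.ndarray:
    """Pairwise maximum over non-overlapping blocks of two.

    Output length is ``floor(L/2)``.  No absolute value is taken: the
    maximum of a negative pair is negative.
    """
    return _as_pairs(signal).max(axis=1)


def decompose_triple(signal) -> PooledTriple:
    """Decompose a signal into its M1/M2/M3 pooled companions.

    Returns average, absolute-average and absolute-maximum pooled signals,
    each of length ``floor(L/2)``.
    """
    pairs = _as_pairs(signal)
    m1 = pairs.mean(axis=1)
    m2 = np.abs(m1)
    m3 = np.abs(pairs).max(axis=1)
    return PooledTriple(m1=m1, m2=m2, m3=m3)
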