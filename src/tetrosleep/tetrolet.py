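"""The L-tetrolet textural pattern operator.

A sliding 16-sample window is laid out row-major as a 4x4 matrix and two
L-shaped tetromino templates (P1, P2) are traced over it.  Each template
partitions the 16 cells into four roles a/b/c/d of four cells each; eight
signum comparisons (a vs c, b vs d) yield an 8-bit code per template, so
every window emits two codes in 0..255.  The two code sequences ("map
signals") are histogrammed over the 256 possible codes and concatenated
into a 512-length textural feature vector.

The comparison is ``1 if p1 - p2 >= 0 else 0`` — ties count as 1 — and bit
``k`` carries weight ``2^(k-1)`` (bit 1 least significant).  Because only
orderings of amplitudes matter, the features are invariant under any
strictly increasing affine rescaling of the signal.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "PatternIndexTable",
    "DEFAULT_TABLE",
    "WINDOW",
    "signum_bit",
    "window_to_matrix",
    "pattern_codes",
    "map_signals",
    "tetrolet_features",
]

#: sliding window length (4x4 matrix)
WINDOW = 16

#: number of features produced per signal (two 256-bin histograms)
N_FEATURES = 512


class PatternIndexTable:
    """Cell-index table of the two L-tetrolet templates.

    For each pattern (P1, P2) and each role (a, b, c, d), holds the four
    1-based cell indices into the row-major 4x4 window matrix.  Within each
    pattern the 16 roles cover every cell exactly once.
    """

    def __init__(self, p1: dict[str, tuple[int, ...]], p2: dict[str, tuple[int, ...]]):
        self.p1 = {r: tuple(v) for r, v in p1.items()}
        self.p2 = {r: tuple(v) for r, v in p2.items()}
        for name, pat in (("P1", self.p1), ("P2", self.p2)):
            cells = sorted(i for role in "abcd" for i in pat[role])
            if cells != list(range(1, 17)):
                raise InvalidInputError(f"{name} roles must cover cells 1..16 exactly once")

    def zero_based(self, pattern: str, role: str) -> np.ndarray:
        pat = self.p1 if pattern == "P1" else self.p2
        return np.asarray(pat[role], dtype=int) - 1


#: canonical template: P1 and P2 L-tetrolet layouts on the 4x4 matrix
DEFAULT_TABLE = PatternIndexTable(
    p1={"a": (1, 5, 9, 10), "b": (4, 3, 2, 6), "c": (16, 12, 8, 7), "d": (13, 14, 15, 11)},
    p2={"a": (1, 5, 6, 7), "b": (8, 4, 3, 2), "c": (9, 13, 14, 15), "d": (16, 12, 11, 10)},
)

_BIT_WEIGHTS = 1 << np.arange(8)  # bit k -> 2^(k-1)


def signum_bit(p1: float, p2: float) -> int:
    """Binary comparison: 1 if ``p1 - p2 >= 0`` else 0 (ties -> 1)."""
    return int(p1 - p2 >= 0)


def window_to_matrix(block) -> np.ndarray:
    """Reshape a 16-sample block row-major into the 4x4 window matrix."""
    b = np.asarray(block, dtype=float)
    if b.shape != (WINDOW,):
        raise InvalidInputError(f"expected a block of {WINDOW} samples, got shape {b.shape}")
    return b.reshape(4, 4)


def pattern_codes(matrix, table: PatternIndexTable = DEFAULT_TABLE) -> tuple[int, int]:
    """8-bit codes of both L-tetrolet patterns for one 4x4 window matrix.

    Bits 1..4 compare role a against role c, bits 5..8 role b against
    role d, in role order.
    """
    flat = np.asarray(matrix, dtype=float).reshape(-1)
    if flat.size != WINDOW:
        raise InvalidInputError("matrix must hold exactly 16 cells")
    codes = []
    for pattern in ("P1", "P2"):
        a, b = flat[table.zero_based(pattern, "a")], flat[table.zero_based(pattern, "b")]
        c, d = flat[table.zero_based(pattern, "c")], flat[table.zero_based(pattern, "d")]
        bits = np.concatenate([(a - c) >= 0, (b - d) >= 0])
        codes.append(int(bits @ _BIT_WEIGHTS))
    return codes[0], codes[1]


def map_signals(signal, table: PatternIndexTable = DEFAULT_TABLE) -> tuple[np.ndarray, np.ndarray]:
    """Code sequences of both patterns over all stride-1 sliding windows.

    Returns two integer arrays of length ``L - 15`` with values in 0..255.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < WINDOW:
        raise InvalidInputError(
            f"need a 1-D signal of at least {WINDOW} samples, got shape {x.shape}"
        )
    wins = np.lib.stride_tricks.sliding_window_view(x, WINDOW)
    maps = []
    for pattern in ("P1", "P2"):
        a = table.zero_based(pattern, "a")
        b = table.zero_based(pattern, "b")
        c = table.zero_based(pattern, "c")
        d = table.zero_based(pattern, "d")
        bits = np.concatenate(
            [(wins[:, a] - wins[:, c]) >= 0, (wins[:, b] - wins[:, d]) >= 0], axis=1
        )
        maps.append((bits @ _BIT_WEIGHTS).astype(np.int64))
    return maps[0], maps[1]


def tetrolet_features(signal, table: PatternIndexTable = DEFAULT_TABLE) -> np.ndarray:
    """512-length textural feature vector of a 1-D signal.

    Concatenates the 256-bin raw-count histograms of the two map signals
    (pattern P1 first).  Each histogram sums to ``L - 15``.
    """
    map1, map2 = map_signals(signal, table)
    hist1 = np.bincount(map1, minlength=256)
    hist2 = np.bincount(map2, minlength=256)
    return np.concatenate([hist1, hist2]).astype(float)
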