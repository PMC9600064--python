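"""Multilevel feature extraction: pooling decomposition x tetrolet x moments.

At each level the current signal is decomposed into its M1/M2/M3 pooled
companions and, for each of the four signals (raw first), a 548-feature
block is emitted: the 512 tetrolet histogram counts, the 18 moments of the
signal and the 18 moments of the tetrolet vector.  The level signal is then
halved with maximum pooling and the procedure repeats.  Five levels yield
the canonical 5 x 4 x 548 = 10,960-length epoch feature vector.

Layout (frozen as layout version ``tetrosleep-v1``): levels outermost,
within a level the signal order is [raw, M1, M2, M3], within a signal the
block order is [tetrolet(512), moments(signal)(18), moments(tetrolet)(18)].
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidInputError
from .moments import N_MOMENTS, compute_moments
from .pooling import decompose_triple, max_pool
from .tetrolet import N_FEATURES, tetrolet_features

__all__ = [
    "LEVEL_WIDTH",
    "LAYOUT_VERSION",
    "min_signal_length",
    "level_features",
    "extract_features",
    "extract_matrix",
    "save_features",
    "load_features",
]

#: features per level: 4 signals x (512 + 18 + 18)
LEVEL_WIDTH = 4 * (N_FEATURES + 2 * N_MOMENTS)

LAYOUT_VERSION = "tetrosleep-v1"


def min_signal_length(levels: int = 5) -> int:
    """Smallest admissible epoch length for ``levels`` levels.

    The level-update halves the signal ``levels - 1`` times and the pooled
    M-signals at the deepest level must still host one 16-sample window,
    hence ``32 * 2**(levels-1)`` samples.
    """
    return 32 * 2 ** (levels - 1)


def _signal_block(signal: np.ndarray) -> np.ndarray:
    tex = tetrolet_features(signal)
    return np.concatenate([tex, compute_moments(signal), compute_moments(tex)])


def level_features(signal) -> np.ndarray:
    """2,192 features of one level: raw signal plus its M1/M2/M3 companions."""
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 32:
        raise InvalidInputError(
            f"level extraction needs >= 32 samples so pooled branches host a window, "
            f"got shape {x.shape}"
        )
    m1, m2, m3 = decompose_triple(x)
    out = np.concatenate([_signal_block(s) for s in (x, m1, m2, m3)])
    assert out.size == LEVEL_WIDTH
    return out


def extract_features(signal, levels: int = 5) -> np.ndarray:
    """Full multilevel feature vector of one epoch (10,960 values at 5 levels)."""
    if levels < 1:
        raise InvalidInputError("levels must be >= 1")
    x = np.asarray(signal, dtype=float)
    need = min_signal_length(levels)
    if x.ndim != 1 or x.size < need:
        raise InvalidInputError(
            f"{levels}-level extraction needs a 1-D signal of at least {need} samples, "
            f"got {x.size if x.ndim == 1 else x.shape}"
        )
    blocks = []
    current = x
    for level in range(levels):
        assert current.size == x.size // 2**level
        blocks.append(level_features(current))
        if level < levels - 1:
            current = max_pool(current)
    return np.concatenate(blocks)


def extract_matrix(epochs, levels: int = 5) -> np.ndarray:
    """Feature matrix (epochs x 2,192·levels) of a sequence of epoch signals."""
    rows = [extract_features(e, levels=levels) for e in epochs]
    if not rows:
        raise InvalidInputError("no epochs supplied")
    return np.vstack(rows)


def _part(prefix: Path, ext: str) -> Path:
    return prefix.parent / (prefix.name + ext)


def save_features(prefix, features, labels, levels: int = 5, provenance=None) -> None:
    """Persist a feature matrix as CSV + label file + JSON header.

    ``prefix`` names the artifact triple ``<prefix>.features.csv``,
    ``<prefix>.labels.txt`` and ``<prefix>.header.json``.
    """
    prefix = Path(prefix)
    X = np.asarray(features, dtype=float)
    labels = list(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise InvalidInputError("features must be 2-D with one label per row")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(X).to_csv(_part(prefix, ".features.csv"), index=False, header=False)
    _part(prefix, ".labels.txt").write_text("\n".join(map(str, labels)) + "\n")
    header = {
        "layout": LAYOUT_VERSION,
        "levels": levels,
        "n_epochs": int(X.shape[0]),
        "n_features": int(X.shape[1]),
        "provenance": provenance if provenance is not None else [],
    }
    _part(prefix, ".header.json").write_text(json.dumps(header, indent=2, sort_keys=True))


def load_features(prefix):
    """Load the artifact triple written by :func:`save_features`.

    Returns ``(features, labels, header)``.
    """
    prefix = Path(prefix)
    try:
        X = pd.read_csv(_part(prefix, ".features.csv"), header=None).to_numpy(dtype=float)
        labels = _part(prefix, ".labels.txt").read_text().split()
        header = json.loads(_part(prefix, ".header.json").read_text())
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot load feature artifacts at {prefix}: {exc}") from exc
    if X.shape[0] != len(labels):
        raise FormatError(
            f"feature matrix has {X.shape[0]} rows but label file has {len(labels)} entries"
        )
    return X, labels, header
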