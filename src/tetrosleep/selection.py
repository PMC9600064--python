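"""TSRFINCA: threshold + positive-ReliefF + iterative-NCA feature selection.

The three-stage hybrid selector:

1. min-max normalize every feature column and drop columns whose sum does
   not exceed a threshold (0 by default — this removes exactly the
   constant columns);
2. weight the survivors with multiclass ReliefF and keep strictly
   positive-weight columns;
3. rank the remainder by diagonal-NCA relevance once, then sweep top-k
   subsets for k in [kmin, kmax], scoring each with the 10-fold
   cross-validated misclassification rate of the cubic SVM, and keep the
   minimum-loss subset (smallest k on ties).

The full trace (per-stage surviving indices, weights, loss curve, chosen
subset) is recorded in a :class:`SelectionTrace` that serializes to JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import EmptySelectionError, InvalidInputError
from .evaluate import cubic_svm
from .nca import nca_weights
from .relieff import relieff_weights

__all__ = [
    "SelectionTrace",
    "minmax_normalize",
    "threshold_select",
    "positive_select",
    "inca_select",
    "tsrfinca",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionTrace:
    """Stage-by-stage record of one TSRFINCA run.

    Index lists are 0-based positions into the columns of the input
    matrix; weights are aligned with the index list of their stage.
    """

    kept_after_threshold: np.ndarray
    relieff_weights: np.ndarray
    kept_after_relieff: np.ndarray
    nca_weights: np.ndarray
    loss_curve: np.ndarray
    kmin: int
    kmax: int
    chosen_k: int
    final_indices: np.ndarray
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        s1, s2, s3 = (
            set(self.kept_after_threshold.tolist()),
            set(self.kept_after_relieff.tolist()),
            set(self.final_indices.tolist()),
        )
        if not (s3 <= s2 <= s1):
            raise AssertionError("selection stages are not nested")
        if len(self.loss_curve) != self.kmax - self.kmin + 1:
            raise AssertionError("loss curve length does not match the k range")
        if self.loss_curve[self.chosen_k - self.kmin] != self.loss_curve.min():
            raise AssertionError("chosen_k does not attain the minimum loss")

    def to_dict(self) -> dict:
        return {
            "kept_after_threshold": self.kept_after_threshold.tolist(),
            "relieff_weights": self.relieff_weights.tolist(),
            "kept_after_relieff": self.kept_after_relieff.tolist(),
            "nca_weights": self.nca_weights.tolist(),
            "loss_curve": self.loss_curve.tolist(),
            "kmin": int(self.kmin),
            "kmax": int(self.kmax),
            "chosen_k": int(self.chosen_k),
            "final_indices": self.final_indices.tolist(),
            "params": self.params,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def save_loss_curve_csv(self, path) -> None:
        lines = ["k,loss"] + [
            f"{k},{float(v)!r}" for k, v in zip(range(self.kmin, self.kmax + 1), self.loss_curve)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "SelectionTrace":
        d = json.loads(Path(path).read_text())
        return cls(
            kept_after_threshold=np.asarray(d["kept_after_threshold"], dtype=int),
            relieff_weights=np.asarray(d["relieff_weights"], dtype=float),
            kept_after_relieff=np.asarray(d["kept_after_relieff"], dtype=int),
            nca_weights=np.asarray(d["nca_weights"], dtype=float),
            loss_curve=np.asarray(d["loss_curve"], dtype=float),
            kmin=int(d["kmin"]),
            kmax=int(d["kmax"]),
            chosen_k=int(d["chosen_k"]),
            final_indices=np.asarray(d["final_indices"], dtype=int),
            params=d.get("params", {}),
        )


def minmax_normalize(matrix) -> np.ndarray:
    """Column-wise min-max scaling into [0, 1]; constant columns map to 0."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"expected a 2-D matrix, got shape {X.shape}")
    mins = X.min(axis=0)
    rng = X.max(axis=0) - mins
    safe = np.where(rng == 0.0, 1.0, rng)
    out = (X - mins) / safe
    out[:, rng == 0.0] = 0.0
    return out


def threshold_select(matrix, beta: float = 0.0):
    """Keep columns whose sum exceeds ``beta`` (input must be normalized).

    With the default ``beta = 0`` this drops exactly the all-zero columns
    that min-max normalization assigns to constant features.
    """
    X = np.asarray(matrix, dtype=float)
    keep = np.flatnonzero(X.sum(axis=0) > beta)
    if keep.size == 0:
        raise EmptySelectionError(f"threshold {beta} removed every feature")
    return X[:, keep], keep


def positive_select(matrix, weights):
    """Keep columns with strictly positive weights."""
    X = np.asarray(matrix, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.shape != (X.shape[1],):
        raise InvalidInputError("one weight per column required")
    keep = np.flatnonzero(w > 0.0)
    if keep.size == 0:
        raise EmptySelectionError("no feature obtained a positive ReliefF weight")
    return X[:, keep], keep


def _cv_loss_curve(X_ranked, y, kmin, kmax, folds, seed) -> np.ndarray:
    """Misclassification rate of the top-k cubic SVM for each k in [kmin, kmax].

    Uses a precomputed polynomial kernel ``(1 + G_k)^3`` whose linear Gram
    ``G_k`` is updated incrementally with the outer product of each newly
    added ranked column — identical to fitting the cubic SVM on the top-k
    columns, but without recomputing k dot products per step.
    """
    n = X_ranked.shape[0]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(n), y))
    G = X_ranked[:, :kmin] @ X_ranked[:, :kmin].T
    losses = np.empty(kmax - kmin + 1)
    for pos, k in enumerate(range(kmin, kmax + 1)):
        if k > kmin:
            col = X_ranked[:, k - 1]
            G += np.outer(col, col)
        K = (1.0 + G) ** 3
        wrong = 0
        for train, test in splits:
            clf = cubic_svm(kernel="precomputed")
            clf.fit(K[np.ix_(train, train)], y[train])
            pred = clf.predict(K[np.ix_(test, train)])
            wrong += int((pred != y[test]).sum())
        losses[pos] = wrong / n
    return losses


def inca_select(
    matrix,
    labels,
    kmin: int = 100,
    kmax: int = 1000,
    folds: int = 10,
    seed: int = 0,
    clamp: bool = True,
    nca_kwargs: dict | None = None,
):
    """Iterative NCA subset search over top-k ranked feature subsets.

    Returns ``(weights, loss_curve, chosen_k, indices, kmin, kmax)`` where
    ``indices`` are positions into the input matrix columns, ``weights``
    the NCA relevance of every input column, and ``kmin/kmax`` the
    (possibly clamped) sweep bounds.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    if not 1 <= kmin <= kmax:
        raise InvalidInputError("need 1 <= kmin <= kmax")
    nf = X.shape[1]
    if nf < kmin:
        if not clamp:
            raise InvalidInputError(f"only {nf} features available but kmin={kmin}")
        logger.warning("clamping kmin=%d, kmax=%d to available features %d", kmin, kmax, nf)
        kmin = kmax = nf
    elif nf < kmax:
        if not clamp:
            raise InvalidInputError(f"only {nf} features available but kmax={kmax}")
        logger.warning("clamping kmax=%d to available features %d", kmax, nf)
        kmax = nf

    weights = nca_weights(X, y, **(nca_kwargs or {}))
    order = np.argsort(-np.abs(weights) ** 2, kind="stable")  # descending relevance
    loss_curve = _cv_loss_curve(np.ascontiguousarray(X[:, order]), y, kmin, kmax, folds, seed)
    chosen_k = kmin + int(np.argmin(loss_curve))  # argmin is first minimum: smallest k
    indices = np.sort(order[:chosen_k])
    return weights, loss_curve, chosen_k, indices, kmin, kmax


def tsrfinca(
    matrix,
    labels,
    beta: float = 0.0,
    relieff_neighbors: int = 10,
    kmin: int = 100,
    kmax: int = 1000,
    folds: int = 10,
    seed: int = 0,
    nca_kwargs: dict | None = None,
) -> SelectionTrace:
    """Run the full three-stage selector and return its trace.

    The matrix is min-max normalized first; all recorded indices refer to
    the columns of the raw input matrix.
    """
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    Xn = minmax_normalize(X)
    X1, idx1 = threshold_select(Xn, beta=beta)
    w_rf = relieff_weights(X1, y, n_neighbors=relieff_neighbors)
    X2, idx2_local = positive_select(X1, w_rf)
    idx2 = idx1[idx2_local]
    w_nca, loss_curve, chosen_k, idx3_local, kmin_eff, kmax_eff = inca_select(
        X2, y, kmin=kmin, kmax=kmax, folds=folds, seed=seed, nca_kwargs=nca_kwargs
    )
    trace = SelectionTrace(
        kept_after_threshold=idx1,
        relieff_weights=w_rf,
        kept_after_relieff=idx2,
        nca_weights=w_nca,
        loss_curve=loss_curve,
        kmin=kmin_eff,
        kmax=kmax_eff,
        chosen_k=chosen_k,
        final_indices=np.sort(idx2[idx3_local]),
        params={
            "beta": beta,
            "relieff_neighbors": relieff_neighbors,
            "folds": folds,
            "seed": seed,
        },
    )
    trace.validate()
    return trace
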