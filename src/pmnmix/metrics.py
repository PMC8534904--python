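"""Clustering-quality and estimation-error metrics.

ACC (clustering accuracy) is the agreement fraction under the best
one-to-one matching of predicted to true cluster labels, found by the
Hungarian algorithm on the confusion matrix.  ARI is the Hubert-Arabie
adjusted Rand index (1 = identical partitions, about 0 for random ones).

SL and FL are the averaged spectral / Frobenius norms of the difference
between estimated and true parameter matrices.  For precisions the
estimate is assembled as the Kronecker product V^{-1} (x) U^{-1} and
compared to the scenario's full pq x pq truth (which need not be
Kronecker-separable; the loss then also quantifies that misspecification).
Components are aligned to the true groups with the accuracy-maximizing
assignment before the losses are computed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from .exceptions import ShapeError

__all__ = [
    "confusion_matrix",
    "clustering_accuracy",
    "adjusted_rand_index",
    "match_components",
    "spectral_loss",
    "frobenius_loss",
    "kron_precision",
]


def _check_labels(truth, pred) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ShapeError(
            f"label vectors must be 1-D and equal length, got {truth.shape} "
            f"and {pred.shape}"
        )
    return truth, pred


def confusion_matrix(truth, pred, G: int | None = None) -> np.ndarray:
    """G x G contingency table; entry (i, j) counts truth i predicted as j."""
    truth, pred = _check_labels(truth, pred)
    if G is None:
        G = int(max(truth.max(), pred.max())) + 1
    C = np.zeros((G, G), dtype=int)
    np.add.at(C, (truth, pred), 1)
    return C


def clustering_accuracy(truth, pred) -> float:
    """ACC: agreement fraction under the optimal label permutation."""
    truth, pred = _check_labels(truth, pred)
    C = confusion_matrix(truth, pred)
    rows, cols = linear_sum_assignment(C, maximize=True)
    return float(C[rows, cols].sum()) / truth.size


def adjusted_rand_index(truth, pred) -> float:
    """Hubert-Arabie adjusted Rand index."""
    truth, pred = _check_labels(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def match_components(truth, pred, G: int | None = None) -> np.ndarray:
    """Accuracy-maximizing assignment of predicted components to true groups.

    Returns ``perm`` with ``perm[j]`` = the true-group index matched to
    predicted component j, so estimated parameter j should be compared
    against truth ``perm[j]``.
    """
    C = confusion_matrix(truth, pred, G)
    rows, cols = linear_sum_assignment(C, maximize=True)
    perm = np.empty(C.shape[0], dtype=int)
    perm[cols] = rows
    return perm


def kron_precision(U_inv: np.ndarray, V_inv: np.ndarray) -> np.ndarray:
    """Precision of vec(X) (column-stacking convention): V^{-1} (x) U^{-1}."""
    return np.kron(V_inv, U_inv)


def _mean_norm_loss(estimated, truth, matching, ord_) -> float:
    est = [np.asarray(A, dtype=float) for A in estimated]
    tru = [np.asarray(A, dtype=float) for A in truth]
    if len(est) != len(tru):
        raise ShapeError("estimated and true lists must have equal length")
    if matching is None:
        matching = np.arange(len(est))
    total = 0.0
    for j, A in enumerate(est):
        B = tru[int(matching[j])]
        if A.shape != B.shape:
            raise ShapeError(
                f"component {j}: estimated {A.shape} vs truth {B.shape}"
            )
        total += np.linalg.norm(A - B, ord_)
    return total / len(est)


def spectral_loss(estimated, truth, matching=None) -> float:
    """SL: mean over components of the largest singular value of the error."""
    return _mean_norm_loss(estimated, truth, matching, 2)


def frobenius_loss(estimated, truth, matching=None) -> float:
    """FL: mean over components of the Frobenius norm of the error.

    Applied to Kronecker-assembled precisions or directly to mean matrices.
    """
    return _mean_norm_loss(estimated, truth, matching, "fro")
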