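"""Evaluation metrics for clustering and embedding recovery.

Partition agreement is scored by the adjusted Rand index (chance-corrected,
in [-1, 1]) and normalized mutual information (in [0, 1]); embedding
recovery by the mean canonical correlation between the estimated and true
latent features; and the information left in the expression matrix about the
labels *given* the embeddings by a residual ("conditional") correlation —
smaller is better.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

_NMI_METHODS = {
    "sqrt": "geometric",
    "min": "min",
    "max": "max",
    "arithmetic": "arithmetic",
}


def _check_pair(a, b):
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape[0] != b.shape[0]:
        raise ValueError("partitions have different lengths")
    return a, b


def ari(y_true, y_pred) -> float:
    """Adjusted Rand index via the permutation-model expectation."""
    a, b = _check_pair(y_true, y_pred)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def nmi(y_true, y_pred, normalization: str = "sqrt") -> float:
    """Normalized mutual information, default sqrt (geometric-mean) variant.

    Conventions for degenerate partitions: both sides single-class -> 1
    (identical trivial partitions); single-class on one side only -> 0.
    """
    a, b = _check_pair(y_true, y_pred)
    if normalization not in _NMI_METHODS:
        raise ValueError(f"unknown normalization {normalization!r}")
    one_a = np.unique(a).size == 1
    one_b = np.unique(b).size == 1
    if one_a and one_b:
        return 1.0
    if one_a or one_b:
        return 0.0
    return float(
        normalized_mutual_info_score(a, b, average_method=_NMI_METHODS[normalization])
    )


def mean_canonical_correlation(Z_hat: np.ndarray, Z_true: np.ndarray) -> float:
    """Mean of the q canonical correlations between two n x q feature sets.

    Both matrices are column-centered; the canonical correlations are the
    singular values of the product of orthonormal column bases, so the score
    is invariant to invertible linear maps (and shifts) of either argument.
    Rank-deficient directions contribute 0 and are logged.
    """
    Z_hat = np.atleast_2d(np.asarray(Z_hat, dtype=float))
    Z_true = np.atleast_2d(np.asarray(Z_true, dtype=float))
    if Z_hat.shape[0] != Z_true.shape[0]:
        raise ValueError("feature matrices must have the same number of rows")
    n = Z_hat.shape[0]
    q = max(Z_hat.shape[1], Z_true.shape[1])
    if n <= q:
        raise ValueError("need more observations than feature dimensions")

    def basis(Z):
        Zc = Z - Z.mean(axis=0, keepdims=True)
        U, s, _ = np.linalg.svd(Zc, full_matrices=False)
        rank = int(np.sum(s > s[0] * max(Z.shape) * np.finfo(float).eps)) if s.size else 0
        return U[:, :rank]

    Ua, Ub = basis(Z_hat), basis(Z_true)
    if min(Ua.shape[1], Ub.shape[1]) < q:
        logger.info(
            "rank-deficient features (%d, %d of %d); missing directions score 0",
            Ua.shape[1], Ub.shape[1], q,
        )
    if Ua.shape[1] == 0 or Ub.shape[1] == 0:
        return 0.0
    s = np.linalg.svd(Ua.T @ Ub, compute_uv=False)
    s = np.clip(s, 0.0, 1.0)
    return float(np.sum(s) / q)


def conditional_correlation(
    X: ExpressionMatrix | np.ndarray,
    y_hat: np.ndarray,
    Z_hat: np.ndarray,
) -> float:
    """Residual association between expression and labels given embeddings.

    Regresses the embeddings (with intercept) out of every gene column and
    out of the one-hot label encoding, then averages over genes the largest
    absolute Pearson correlation between the gene residual and any label
    indicator residual.  Lies in [0, 1]; 0 means the embeddings already
    carry all label information present in the expression.
    """
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    y_hat = np.asarray(y_hat).ravel()
    Z_hat = np.atleast_2d(np.asarray(Z_hat, dtype=float))
    n = Xv.shape[0]
    if y_hat.shape[0] != n or Z_hat.shape[0] != n:
        raise ValueError("shapes of X, y_hat, Z_hat disagree")
    classes = np.unique(y_hat)
    Y = (y_hat[:, None] == classes[None, :]).astype(float)
    D = np.column_stack([np.ones(n), Z_hat])
    coefX, *_ = np.linalg.lstsq(D, Xv, rcond=None)
    coefY, *_ = np.linalg.lstsq(D, Y, rcond=None)
    RX = Xv - D @ coefX
    RY = Y - D @ coefY

    def _unitize(M):
        nrm = np.linalg.norm(M, axis=0)
        keep = nrm > 1e-12 * max(1.0, np.abs(M).max())
        out = np.zeros_like(M)
        out[:, keep] = M[:, keep] / nrm[keep]
        return out, keep

    RXu, keepX = _unitize(RX - RX.mean(axis=0, keepdims=True))
    RYu, keepY = _unitize(RY - RY.mean(axis=0, keepdims=True))
    if not keepY.any():
        return 0.0
    corr = np.abs(RXu.T @ RYu)          # p x K
    per_gene = corr.max(axis=1)
    per_gene[~keepX] = 0.0              # constant residual -> contributes 0
    return float(np.clip(per_gene.mean(), 0.0, 1.0))
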