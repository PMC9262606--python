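"""Tandem (two-step) baselines the joint model is compared against."""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .types import ExpressionMatrix


def pca_scores(X: ExpressionMatrix | np.ndarray, q: int, seed: int = 0) -> np.ndarray:
    """Top-q ordinary PCA scores of the centered expression matrix."""
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    pca = PCA(n_components=q, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(Xv)


def tandem_pca_gmm(
    X: ExpressionMatrix | np.ndarray, K: int, q: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential pipeline: PCA to q dimensions, then a K-component GMM.

    Returns (labels in 1..K, PCA scores).
    """
    scores = pca_scores(X, q, seed)
    gmm = GaussianMixture(
        n_components=K, covariance_type="full", random_state=seed, n_init=1,
        reg_covar=1e-6,
    )
    labels = gmm.fit_predict(scores) + 1
    return labels, scores
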