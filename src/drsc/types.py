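"""Core data containers shared across the package.

Conventions
-----------
* Expression matrices are dense ``float64`` arrays of shape ``(n_spots,
  n_genes)`` holding log-normalized, gene-centered values.
* Cluster labels are 1-based integers in ``1..K`` in every public API
  (matching the usual statistical notation); internal kernels use 0-based
  arrays and convert at the boundary.
* Neighbor graphs are undirected, without self loops, stored in CSR form so
  the numba kernels can walk them cheaply.  A graph with zero edges denotes
  non-spatial data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their domain constraints."""


def _as_ids(ids: Sequence[str] | None, n: int, prefix: str) -> np.ndarray:
    if ids is None:
        width = len(str(n))
        return np.array([f"{prefix}{i + 1:0{width}d}" for i in range(n)])
    out = np.asarray(ids, dtype=object)
    if out.shape[0] != n:
        raise ValueError(f"expected {n} {prefix} ids, got {out.shape[0]}")
    return out


@dataclass
class ExpressionMatrix:
    """Spots/cells x genes matrix of log-normalized expression values.

    The model layer assumes each gene column has mean (close to) zero; use
    :meth:`center` to enforce that after log-normalization.
    """

    values: np.ndarray
    spot_ids: np.ndarray = None
    gene_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2 or p < 2:
            raise ValueError(f"need at least 2 spots and 2 genes, got {n}x{p}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite entries")
        self.spot_ids = _as_ids(self.spot_ids, n, "spot_")
        self.gene_ids = _as_ids(self.gene_ids, p, "gene_")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def is_centered(self, tol: float = 1e-8) -> bool:
        return bool(np.max(np.abs(self.values.mean(axis=0))) <= tol)

    def center(self) -> "ExpressionMatrix":
        """Return a copy with every gene column shifted to mean zero."""
        return ExpressionMatrix(
            self.values - self.values.mean(axis=0, keepdims=True),
            self.spot_ids,
            self.gene_ids,
        )


@dataclass
class NeighborGraph:
    """Symmetric adjacency over spots; zero edges means non-spatial mode."""

    adjacency: sp.csr_matrix
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        adj = sp.csr_matrix(self.adjacency)
        adj.data = np.ones_like(adj.data)
        if adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency must not contain self-loops")
        self.adjacency = adj
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (adj.shape[0], 2):
                raise ValueError("coords must be n x 2")

    @classmethod
    def empty(cls, n: int, coords: np.ndarray | None = None) -> "NeighborGraph":
        return cls(sp.csr_matrix((n, n)), coords)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def is_empty(self) -> bool:
        return self.adjacency.nnz == 0

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def neighbor_sets(self) -> list[np.ndarray]:
        """The index set N_i for every spot i."""
        a = self.adjacency
        return [a.indices[a.indptr[i]:a.indptr[i + 1]] for i in range(self.n)]

    def csr_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.adjacency.indptr.astype(np.int64),
            self.adjacency.indices.astype(np.int64),
        )

    def label_counts(self, y0: np.ndarray, K: int) -> np.ndarray:
        """c[i, k] = number of neighbors of spot i carrying (0-based) label k."""
        n = self.n
        if self.is_empty:
            return np.zeros((n, K))
        onehot = np.zeros((n, K))
        onehot[np.arange(n), y0] = 1.0
        return self.adjacency @ onehot


@dataclass
class ModelParams:
    """Parameters of the hierarchical factor-mixture model.

    W : (p, q) loading matrix of the probabilistic-PCA layer.
    Lambda : (p,) positive residual variances (diagonal of the noise cov).
    mu : (K, q) class means of the latent embeddings.
    Sigma : (K, q, q) class covariances, each symmetric positive definite.
    beta : nonnegative Potts smoothness; 0 removes all spatial coupling.
    """

    W: np.ndarray
    Lambda: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    beta: float = 0.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.Lambda = np.asarray(self.Lambda, dtype=np.float64).ravel()
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=np.float64))
        self.Sigma = np.asarray(self.Sigma, dtype=np.float64)
        if self.Sigma.ndim == 2:
            self.Sigma = self.Sigma[None, :, :]
        self.beta = float(self.beta)

    @property
    def p(self) -> int:
        return self.W.shape[0]

    @property
    def q(self) -> int:
        return self.W.shape[1]

    @property
    def K(self) -> int:
        return self.mu.shape[0]

    def validate(self) -> None:
        p, q, K = self.p, self.q, self.K
        if self.Lambda.shape != (p,):
            raise InvalidParameterError("Lambda must have one entry per gene")
        if np.any(self.Lambda <= 0):
            raise InvalidParameterError("residual variances must be positive")
        if self.mu.shape != (K, q) or self.Sigma.shape != (K, q, q):
            raise InvalidParameterError("mu/Sigma shapes inconsistent with W")
        for k in range(K):
            S = self.Sigma[k]
            if not np.allclose(S, S.T, atol=1e-10):
                raise InvalidParameterError(f"Sigma[{k}] is not symmetric")
            try:
                np.linalg.cholesky(S)
            except np.linalg.LinAlgError as err:
                raise InvalidParameterError(
                    f"Sigma[{k}] is not positive definite"
                ) from err
        if not np.isfinite(self.beta) or self.beta < 0:
            raise InvalidParameterError("beta must be a nonnegative real")

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.W.copy(), self.Lambda.copy(), self.mu.copy(),
            self.Sigma.copy(), self.beta,
        )


@dataclass
class FitResult:
    """Output of the joint dimension-reduction / clustering fit.

    labels : (n,) hard assignments in 1..K, the row-argmax of
        ``responsibilities``.
    responsibilities : (n, K) row-stochastic posterior class weights.
    embeddings : (n, q) posterior means of the latent features.
    embedding_covs : (K, q, q) per-class posterior covariances.
    loglik : observed-data log-likelihood part of the objective (the Potts
        pseudo-prior term removed), used by model selection.
    """

    labels: np.ndarray
    responsibilities: np.ndarray
    embeddings: np.ndarray
    embedding_covs: np.ndarray
    params: ModelParams
    objective_trace: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    mbic: float = np.nan
    class_means: np.ndarray | None = None  # (n, K, q) per-class posterior means

    @property
    def K(self) -> int:
        return self.responsibilities.shape[1]

    @property
    def q(self) -> int:
        return self.embeddings.shape[1]


@dataclass
class SimulationTruth:
    """Ground truth attached to a simulated dataset."""

    y: np.ndarray              # (n,) labels in 1..K
    z: np.ndarray              # (n, q) latent features
    W: np.ndarray              # (p, q) orthonormal-column loading
    Lambda: np.ndarray         # (p,) residual variances
    beta_true: float
    tau: np.ndarray | None = None  # (p,) gene offsets (count scenario only)
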