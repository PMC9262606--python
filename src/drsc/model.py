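"""Joint dimension reduction and (spatial) clustering by ICM-EM.

Model
-----
For each spot i with centered log-normalized expression x_i (p genes):

    x_i | z_i          ~  N(W z_i, Lambda),        Lambda diagonal
    z_i | y_i = k      ~  N(mu_k, Sigma_k)
    y = (y_1..y_n)     ~  Potts(beta) on the neighbor graph

so marginally x_i | y_i = k ~ N(W mu_k, W Sigma_k W^T + Lambda).  The first
layer is a probabilistic PCA giving q-dimensional embeddings; the second is a
Gaussian mixture over the embeddings whose labels are smoothed by a hidden
Markov random field.  With an empty graph (or beta = 0) the model reduces to
a latent Gaussian mixture with no spatial coupling.

Fitting interleaves ICM label sweeps, neighbor-aware responsibilities, exact
E/M updates of (W, Lambda, mu, Sigma), and a grid update of beta maximizing
the Potts pseudo-likelihood.  The traced objective is the pseudo-marginal

    F = sum_i [ lse_k(ll_ik + beta c_ik) - lse_k(beta c_ik) ]

with ll_ik the class marginal log density and c_ik the count of neighbors of
i carrying label k.  The M-step and the beta grid step increase F by EM /
minorize-maximize arguments; ICM label proposals are accepted only when they
do not decrease F, so the trace is non-decreasing by construction.  All
Gaussian evaluations use the Woodbury identity and matrix-determinant lemma;
no p x p matrix is ever formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from ._kernels import icm_kernel
from .types import ExpressionMatrix, FitResult, ModelParams, NeighborGraph

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)

DEFAULT_BETA_GRID = np.round(np.arange(0.0, 4.0 + 1e-9, 0.2), 10)


# ---------------------------------------------------------------------------
# likelihood layer
# ---------------------------------------------------------------------------

def class_logliks(X: np.ndarray, params: ModelParams) -> np.ndarray:
    """(n, K) matrix of log N(x_i; W mu_k, W Sigma_k W^T + Lambda).

    Uses the Woodbury identity / determinant lemma so the cost is
    O(npq + K(nq^2 + q^3)) and only q x q systems are solved.
    """
    params.validate()
    W, lam, mu, Sigma = params.W, params.Lambda, params.mu, params.Sigma
    n, p = X.shape
    K, q = mu.shape
    Li = 1.0 / lam
    XL = X * Li                       # n x p
    a = np.einsum("ij,ij->i", XL, X)  # x^T Lam^-1 x
    U = XL @ W                        # n x q, rows = W^T Lam^-1 x_i
    G = W.T @ (W * Li[:, None])       # q x q, W^T Lam^-1 W
    logdet_lam = float(np.sum(np.log(lam)))
    out = np.empty((n, K))
    for k in range(K):
        cS = cho_factor(Sigma[k], lower=True)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
        Sinv = cho_solve(cS, np.eye(q))
        M = Sinv + G
        cM = cho_factor(M, lower=True)
        logdet_M = 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
        logdet_C = logdet_lam + logdet_S + logdet_M
        Gmu = G @ mu[k]
        T = U - Gmu                   # W^T Lam^-1 (x_i - W mu_k)
        MT = cho_solve(cM, T.T).T
        quad = (
            a
            - 2.0 * U @ mu[k]
            + mu[k] @ Gmu
            - np.einsum("ij,ij->i", T, MT)
        )
        out[:, k] = -0.5 * (p * _LOG2PI + logdet_C + quad)
    return out


def class_marginal_loglik(x: np.ndarray, params: ModelParams, k: int) -> float:
    """Log marginal density of one expression vector under class k (1-based)."""
    if not 1 <= k <= params.K:
        raise ValueError(f"class index k={k} outside 1..{params.K}")
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != params.p:
        raise ValueError("x length does not match the number of genes")
    return float(class_logliks(x[None, :], params)[0, k - 1])


# ---------------------------------------------------------------------------
# label layer
# ---------------------------------------------------------------------------

def _icm_from_logliks(
    loglik: np.ndarray,
    beta: float,
    graph: NeighborGraph,
    y0: np.ndarray,
    max_sweeps: int,
) -> np.ndarray:
    y = y0.astype(np.int64).copy()
    if graph.is_empty or beta == 0.0:
        return np.argmax(loglik, axis=1)
    indptr, indices = graph.csr_arrays()
    icm_kernel(loglik, float(beta), indptr, indices, y, int(max_sweeps))
    return y


def icm_sweep(
    X: ExpressionMatrix,
    graph: NeighborGraph,
    params: ModelParams,
    y: np.ndarray,
    max_sweeps: int = 10,
) -> np.ndarray:
    """Coordinate-ascent label update (labels 1-based in and out).

    Spots are visited in ascending index order; each y_i is set to the class
    maximizing ``class log-density + beta * (# neighbors with that label)``
    given the *current* neighbor labels, ties to the smallest class.  Sweeps
    repeat until no label changes or ``max_sweeps`` is reached.
    """
    y0 = _check_labels(y, params.K, X.n_spots)
    ll = class_logliks(X.values, params)
    return _icm_from_logliks(ll, params.beta, graph, y0, max_sweeps) + 1


def _check_labels(y: np.ndarray, K: int, n: int) -> np.ndarray:
    y = np.asarray(y).ravel().astype(np.int64)
    if y.shape[0] != n:
        raise ValueError("label vector has wrong length")
    if y.min() < 1 or y.max() > K:
        raise ValueError(f"labels must lie in 1..{K}")
    return y - 1


def _responsibilities_from(
    loglik: np.ndarray, beta: float, counts: np.ndarray
) -> np.ndarray:
    logits = loglik + beta * counts
    logits -= logits.max(axis=1, keepdims=True)
    R = np.exp(logits)
    R /= R.sum(axis=1, keepdims=True)
    return R


def responsibilities(
    X: ExpressionMatrix,
    graph: NeighborGraph,
    params: ModelParams,
    y: np.ndarray,
) -> np.ndarray:
    """Soft class weights R[i, k] ∝ exp(ll_ik + beta c_ik), rows sum to 1."""
    y0 = _check_labels(y, params.K, X.n_spots)
    ll = class_logliks(X.values, params)
    counts = graph.label_counts(y0, params.K)
    return _responsibilities_from(ll, params.beta, counts)


# ---------------------------------------------------------------------------
# E and M steps
# ---------------------------------------------------------------------------

def estep_embeddings(
    X: ExpressionMatrix | np.ndarray,
    params: ModelParams,
    R: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior moments of the latent embeddings.

    Returns ``(m, S, z_hat)`` with m[i, k] = S_k (Sigma_k^-1 mu_k +
    W^T Lam^-1 x_i), S_k = (Sigma_k^-1 + W^T Lam^-1 W)^-1, and the collapsed
    means z_hat_i = sum_k R[i, k] m[i, k].
    """
    params.validate()
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    W, lam, mu, Sigma = params.W, params.Lambda, params.mu, params.Sigma
    K, q = mu.shape
    n = Xv.shape[0]
    U = (Xv / lam) @ W
    G = W.T @ (W / lam[:, None])
    m = np.empty((n, K, q))
    S = np.empty((K, q, q))
    for k in range(K):
        cS = cho_factor(Sigma[k], lower=True)
        Sinv = cho_solve(cS, np.eye(q))
        M = Sinv + G
        cM = cho_factor(M, lower=True)
        S[k] = cho_solve(cM, np.eye(q))
        S[k] = 0.5 * (S[k] + S[k].T)
        b = Sinv @ mu[k]
        m[:, k, :] = cho_solve(cM, (U + b).T).T
    z_hat = np.einsum("ik,ikq->iq", R, m)
    return m, S, z_hat


def mstep_update(
    X: ExpressionMatrix | np.ndarray,
    R: np.ndarray,
    m: np.ndarray,
    S: np.ndarray,
    params: ModelParams,
    var_floor: float = 1e-8,
    sigma_ridge: float = 1e-6,
) -> ModelParams:
    """Weighted maximum-likelihood updates of (mu, Sigma, W, Lambda).

    beta is left untouched (it has its own grid step).  A cluster whose
    responsibility mass falls below 1e-8 keeps its previous mu_k / Sigma_k
    and is reported in the log; K is never reduced.
    """
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    n, p = Xv.shape
    K, q = params.mu.shape
    Nk = R.sum(axis=0)
    mbar = np.einsum("ik,ikq->iq", R, m)

    mu_new = params.mu.copy()
    Sigma_new = params.Sigma.copy()
    B = np.zeros((q, q))          # sum_ik R_ik (m m^T + S_k)
    for k in range(K):
        Rm = R[:, k][:, None] * m[:, k, :]
        second = m[:, k, :].T @ Rm  # sum_i R_ik m m^T
        B += second + Nk[k] * S[k]
        if Nk[k] < 1e-8:
            logger.warning("cluster %d received ~zero mass; parameters kept", k + 1)
            continue
        mu_k = Rm.sum(axis=0) / Nk[k]
        D = m[:, k, :] - mu_k
        C = (D * R[:, k][:, None]).T @ D / Nk[k] + S[k]
        C = 0.5 * (C + C.T)
        ev_min = np.linalg.eigvalsh(C)[0]
        if ev_min < 1e-8:
            C = C + sigma_ridge * np.eye(q)
        mu_new[k] = mu_k
        Sigma_new[k] = C

    A = Xv.T @ mbar               # p x q
    W_new = np.linalg.solve(B, A.T).T
    lam_new = (
        np.einsum("ij,ij->j", Xv, Xv)
        - 2.0 * np.einsum("jq,jq->j", A, W_new)
        + np.einsum("jq,jq->j", W_new @ B, W_new)
    ) / n
    lam_new = np.maximum(lam_new, var_floor)
    return ModelParams(W_new, lam_new, mu_new, Sigma_new, params.beta)


# ---------------------------------------------------------------------------
# beta grid update
# ---------------------------------------------------------------------------

def potts_pseudo_loglik(
    beta: float, counts: np.ndarray, R: np.ndarray
) -> float:
    """PL(beta) = sum_i [ sum_k R_ik beta c_ik - lse_k(beta c_ik) ]."""
    bc = beta * counts
    return float(np.sum(R * bc) - np.sum(logsumexp(bc, axis=1)))


def update_beta(
    graph: NeighborGraph,
    R: np.ndarray,
    y: np.ndarray,
    beta_grid: np.ndarray = DEFAULT_BETA_GRID,
) -> float:
    """Grid maximizer of the Potts pseudo-likelihood; ties -> smaller beta.

    An empty graph short-circuits to 0 without touching the grid.
    """
    if graph.is_empty:
        return 0.0
    beta_grid = np.asarray(beta_grid, dtype=np.float64)
    if beta_grid.size == 0:
        raise ValueError("beta_grid must be non-empty")
    K = R.shape[1]
    y0 = _check_labels(y, K, R.shape[0])
    counts = graph.label_counts(y0, K)
    vals = np.array([potts_pseudo_loglik(b, counts, R) for b in beta_grid])
    return float(beta_grid[int(np.argmax(vals))])


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Knobs of the outer ICM-EM loop (defaults documented in docs/methods.md)."""

    max_iter: int = 30
    tol: float = 1e-5
    beta_grid: np.ndarray = field(default_factory=lambda: DEFAULT_BETA_GRID.copy())
    fix_beta: float | None = None
    seed: int = 0
    init: np.ndarray | None = None   # optional initial labels (1-based)
    icm_sweeps: int = 10
    kmeans_n_init: int = 10


def initialize_params(
    X: ExpressionMatrix,
    K: int,
    q: int,
    seed: int = 0,
    init_labels: np.ndarray | None = None,
    spatial: bool = False,
    kmeans_n_init: int = 10,
) -> tuple[ModelParams, np.ndarray]:
    """PCA + k-means initialization.

    Ordinary PCA to q dimensions provides the initial loading and residual
    variances; k-means on the scores (or user-supplied labels) provides the
    initial partition, whose within-cluster moments seed mu_k / Sigma_k.
    Returns (params, labels0) with labels 1-based.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    Xv = X.values
    n, p = Xv.shape
    pca = PCA(n_components=q, svd_solver="randomized", random_state=seed)
    scores = pca.fit_transform(Xv)
    W0 = pca.components_.T
    resid = Xv - scores @ pca.components_
    lam0 = np.maximum(resid.var(axis=0), 1e-8)
    if init_labels is not None:
        y0 = _check_labels(init_labels, K, n)
    else:
        km = KMeans(n_clusters=K, n_init=kmeans_n_init, random_state=seed)
        y0 = km.fit_predict(scores).astype(np.int64)
    mu0 = np.zeros((K, q))
    Sigma0 = np.tile(np.eye(q), (K, 1, 1))
    for k in range(K):
        mask = y0 == k
        if mask.sum() >= 2:
            mu0[k] = scores[mask].mean(axis=0)
            C = np.cov(scores[mask].T, bias=True)
            C = np.atleast_2d(C)
            if np.linalg.eigvalsh(C)[0] < 1e-8:
                C = C + 1e-6 * np.eye(q)
            Sigma0[k] = 0.5 * (C + C.T)
        elif mask.sum() == 1:
            mu0[k] = scores[mask][0]
    beta0 = 1.0 if spatial else 0.0
    return ModelParams(W0, lam0, mu0, Sigma0, beta0), y0 + 1


# ---------------------------------------------------------------------------
# main fit loop
# ---------------------------------------------------------------------------

def _objective(loglik: np.ndarray, beta: float, counts: np.ndarray) -> float:
    """F = sum_i [ lse_k(ll + beta c) - lse_k(beta c) ]."""
    if beta == 0.0:
        K = loglik.shape[1]
        return float(np.sum(logsumexp(loglik, axis=1)) - loglik.shape[0] * np.log(K))
    bc = beta * counts
    return float(
        np.sum(logsumexp(loglik + bc, axis=1)) - np.sum(logsumexp(bc, axis=1))
    )


def fit_drsc(
    X: ExpressionMatrix,
    graph: NeighborGraph | None,
    K: int,
    q: int,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the joint dimension-reduction / spatial-clustering model.

    With an empty (or absent) graph, or ``fix_beta=0``, beta is held at 0 and
    the procedure is exactly EM for a latent Gaussian mixture on the
    probabilistic-PCA layer.  The returned ``objective_trace`` is
    non-decreasing up to numerical tolerance.
    """
    opts = options or FitOptions()
    n, p = X.n_spots, X.n_genes
    if K < 1 or K > n:
        raise ValueError(f"K must lie in 1..n, got {K}")
    if not 1 <= q < min(n, p):
        raise ValueError(f"q must satisfy 1 <= q < min(n, p) = {min(n, p)}")
    if graph is None:
        graph = NeighborGraph.empty(n)
    if graph.n != n:
        raise ValueError("graph size does not match the expression matrix")
    if not X.is_centered():
        logger.info("gene columns not centered; centering internally")
        X = X.center()

    spatial = (not graph.is_empty) and (opts.fix_beta is None or opts.fix_beta > 0)
    params, y1 = initialize_params(
        X, K, q, seed=opts.seed, init_labels=opts.init,
        spatial=spatial and opts.fix_beta is None,
        kmeans_n_init=opts.kmeans_n_init,
    )
    if opts.fix_beta is not None:
        params.beta = float(opts.fix_beta)
    if graph.is_empty:
        params.beta = 0.0
    y0 = y1 - 1

    beta_grid = np.asarray(opts.beta_grid, dtype=np.float64)
    trace: list[float] = []
    converged = False
    n_iter = 0
    ll = counts = R = None
    for t in range(opts.max_iter):
        n_iter = t + 1
        ll = class_logliks(X.values, params)
        # ICM proposal, accepted only if it does not lower the objective
        if spatial and params.beta > 0:
            y_prop = _icm_from_logliks(ll, params.beta, graph, y0, opts.icm_sweeps)
            c_prop = graph.label_counts(y_prop, K)
            c_cur = graph.label_counts(y0, K)
            if _objective(ll, params.beta, c_prop) >= _objective(ll, params.beta, c_cur):
                y0, counts = y_prop, c_prop
            else:
                counts = c_cur
        else:
            y0 = np.argmax(ll, axis=1)
            counts = graph.label_counts(y0, K)
        R = _responsibilities_from(ll, params.beta, counts)
        obj = _objective(ll, params.beta, counts)
        trace.append(obj)
        if t > 0 and abs(trace[-1] - trace[-2]) < opts.tol * (abs(trace[-2]) + 1e-10):
            converged = True
            break
        m, S, _ = estep_embeddings(X, params, R)
        params = mstep_update(X, R, m, S, params)
        if spatial and opts.fix_beta is None:
            cand = update_beta(graph, R, y0 + 1, beta_grid)
            # ascent guard for grids that do not contain the current beta
            if potts_pseudo_loglik(cand, counts, R) >= potts_pseudo_loglik(
                params.beta, counts, R
            ):
                params.beta = cand

    # finalization at the last parameter values
    ll = class_logliks(X.values, params)
    if spatial and params.beta > 0:
        y_prop = _icm_from_logliks(ll, params.beta, graph, y0, opts.icm_sweeps)
        c_prop = graph.label_counts(y_prop, K)
        c_cur = graph.label_counts(y0, K)
        if _objective(ll, params.beta, c_prop) >= _objective(ll, params.beta, c_cur):
            y0, counts = y_prop, c_prop
        else:
            counts = c_cur
    else:
        y0 = np.argmax(ll, axis=1)
        counts = graph.label_counts(y0, K)
    R = _responsibilities_from(ll, params.beta, counts)
    trace.append(_objective(ll, params.beta, counts))
    m, S, z_hat = estep_embeddings(X, params, R)
    labels = np.argmax(R, axis=1) + 1
    # observed-data log-likelihood with the Potts pseudo-prior removed:
    # F - PL(beta) = sum_ik R_ik ll_ik + H(R) at the E-step point
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.sum(np.where(R > 0, R * np.log(R), 0.0))
    loglik_hat = float(np.sum(R * ll) + entropy)
    return FitResult(
        labels=labels,
        responsibilities=R,
        embeddings=z_hat,
        embedding_covs=S,
        params=params,
        objective_trace=np.asarray(trace),
        loglik=loglik_hat,
        n_iter=n_iter,
        converged=converged,
        class_means=m,
    )
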