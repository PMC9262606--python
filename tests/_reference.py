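"""Independent reference implementations used as test oracles.

Everything here deliberately takes the *naive* route — dense covariance
matrices, explicit joint-Gaussian conditioning, per-site Python loops,
exhaustive enumeration — so that agreement with the package's optimized
paths (Woodbury identity, numba kernels, grid searches) is an informative
check rather than a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal


# ---------------------------------------------------------------------------
# dense-covariance Gaussian evaluation
# ---------------------------------------------------------------------------

def dense_class_loglik(x, W, lam, mu_k, Sigma_k) -> float:
    """log N(x; W mu_k, W Sigma_k W^T + diag(lam)) via the full p x p cov."""
    C = W @ Sigma_k @ W.T + np.diag(lam)
    return float(multivariate_normal(mean=W @ mu_k, cov=C).logpdf(x))


def dense_conditional_moments(x, W, lam, mu_k, Sigma_k):
    """E[z | x, y=k] and Cov[z | x, y=k] by conditioning the joint Gaussian."""
    C = W @ Sigma_k @ W.T + np.diag(lam)
    cross = Sigma_k @ W.T            # Cov(z, x)
    Cinv = np.linalg.inv(C)
    m = mu_k + cross @ Cinv @ (x - W @ mu_k)
    S = Sigma_k - cross @ Cinv @ cross.T
    return m, S


# ---------------------------------------------------------------------------
# ICM coordinate ascent, simulated step by step
# ---------------------------------------------------------------------------

def icm_by_hand(loglik, beta, neighbor_sets, y0, max_sweeps=10):
    """Sequential coordinate ascent over an explicit neighbor list.

    Visits sites in ascending order; each site takes the argmax of
    class score + beta * (neighbors currently sharing that class), ties to
    the smallest class.  0-based labels.
    """
    y = list(y0)
    n, K = loglik.shape
    for _ in range(max_sweeps):
        changed = False
        for i in range(n):
            scores = []
            for k in range(K):
                agree = sum(1 for j in neighbor_sets[i] if y[j] == k)
                scores.append(loglik[i, k] + beta * agree)
            best = max(range(K), key=lambda k: (scores[k], -k))
            if best != y[i]:
                y[i] = best
                changed = True
        if not changed:
            break
    return np.array(y)


# ---------------------------------------------------------------------------
# expected complete-data log-likelihood (Q function)
# ---------------------------------------------------------------------------

def q_function(X, R, m, S, W, lam, mu, Sigma) -> float:
    """Q = sum_ik R_ik E[ log p(x_i | z) + log p(z | y=k) ] under the
    posterior moments (m, S) held fixed."""
    n, p = X.shape
    K, q = mu.shape
    total = 0.0
    for k in range(K):
        Sig_inv = np.linalg.inv(Sigma[k])
        _, logdet_sig = np.linalg.slogdet(Sigma[k])
        for i in range(n):
            r = R[i, k]
            if r == 0:
                continue
            mi = m[i, k]
            resid = X[i] - W @ mi
            # E[(x_ij - w_j'z)^2] = resid_j^2 + w_j' S_k w_j
            corr = np.einsum("jq,ql,jl->j", W, S[k], W)
            e_obs = -0.5 * np.sum(
                np.log(2 * np.pi * lam) + (resid**2 + corr) / lam
            )
            d = mi - mu[k]
            e_lat = -0.5 * (
                q * np.log(2 * np.pi)
                + logdet_sig
                + d @ Sig_inv @ d
                + np.trace(Sig_inv @ S[k])
            )
            total += r * (e_obs + e_lat)
    return total


# ---------------------------------------------------------------------------
# latent Gaussian mixture EM with the spatial terms deleted
# ---------------------------------------------------------------------------

def latent_gmm_em(X, params, max_iter=30, tol=1e-5):
    """EM for the factor-mixture model with no spatial coupling.

    Mirrors the joint fitter's loop structure (same stopping rule, same
    update formulas) but evaluates every Gaussian through the dense p x p
    covariance and explicit joint-Gaussian conditioning.  Mixture weights
    are uniform 1/K (the model has no learned mixing proportions).
    Returns (final objective, trace).
    """
    X = np.asarray(X, float)
    n, p = X.shape
    W, lam = params.W.copy(), params.Lambda.copy()
    mu, Sigma = params.mu.copy(), params.Sigma.copy()
    K, q = mu.shape
    trace = []
    for t in range(max_iter):
        ll = np.column_stack(
            [
                multivariate_normal(
                    mean=W @ mu[k], cov=W @ Sigma[k] @ W.T + np.diag(lam)
                ).logpdf(X)
                for k in range(K)
            ]
        )
        obj = float(np.sum(logsumexp(ll, axis=1)) - n * np.log(K))
        trace.append(obj)
        if t > 0 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-10):
            break
        shifted = ll - ll.max(axis=1, keepdims=True)
        R = np.exp(shifted)
        R /= R.sum(axis=1, keepdims=True)
        m = np.empty((n, K, q))
        S = np.empty((K, q, q))
        for k in range(K):
            cross = Sigma[k] @ W.T
            Cinv = np.linalg.inv(W @ Sigma[k] @ W.T + np.diag(lam))
            S[k] = Sigma[k] - cross @ Cinv @ cross.T
            m[:, k, :] = mu[k] + (X - W @ mu[k]) @ Cinv @ cross.T
        Nk = R.sum(axis=0)
        B = np.zeros((q, q))
        for k in range(K):
            Rm = R[:, k][:, None] * m[:, k, :]
            B += m[:, k, :].T @ Rm + Nk[k] * S[k]
            if Nk[k] < 1e-8:
                continue
            mu[k] = Rm.sum(axis=0) / Nk[k]
            D = m[:, k, :] - mu[k]
            C = (D * R[:, k][:, None]).T @ D / Nk[k] + S[k]
            C = 0.5 * (C + C.T)
            if np.linalg.eigvalsh(C)[0] < 1e-8:
                C = C + 1e-6 * np.eye(q)
            Sigma[k] = C
        A = X.T @ np.einsum("ik,ikq->iq", R, m)
        W = np.linalg.solve(B, A.T).T
        lam = (
            np.einsum("ij,ij->j", X, X)
            - 2.0 * np.einsum("jq,jq->j", A, W)
            + np.einsum("jq,jq->j", W @ B, W)
        ) / n
        lam = np.maximum(lam, 1e-8)
    ll = np.column_stack(
        [
            multivariate_normal(
                mean=W @ mu[k], cov=W @ Sigma[k] @ W.T + np.diag(lam)
            ).logpdf(X)
            for k in range(K)
        ]
    )
    final = float(np.sum(logsumexp(ll, axis=1)) - n * np.log(K))
    trace.append(final)
    return final, np.array(trace)


# ---------------------------------------------------------------------------
# combinatorics
# ---------------------------------------------------------------------------

def all_partitions(n):
    """Every set partition of n items as a label vector (restricted growth)."""
    def rec(prefix, m):
        i = len(prefix)
        if i == n:
            yield np.array(prefix)
            return
        for k in range(m + 1):
            yield from rec(prefix + [k], max(m, k + 1))

    yield from rec([], 0)


def potts_2x2_exact_probs(beta, K=2):
    """Exact distribution of the 2x2-lattice Potts model by enumeration.

    Edges of the 4-neighbor 2x2 lattice (row-major): (0,1), (0,2), (1,3),
    (2,3).  Pr(y) ∝ exp(beta * #{agreeing edges}).
    """
    edges = [(0, 1), (0, 2), (1, 3), (2, 3)]
    configs = list(itertools.product(range(K), repeat=4))
    w = np.array(
        [np.exp(beta * sum(y[a] == y[b] for a, b in edges)) for y in configs]
    )
    return configs, w / w.sum()


def batch_means_se(indicator, n_batches=200):
    """Monte-Carlo SE of a mean of a correlated 0/1 series via batch means."""
    m = len(indicator) // n_batches
    batches = np.asarray(indicator[: m * n_batches]).reshape(n_batches, m).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def plugin_nmi_sqrt(a, b):
    """Plug-in empirical MI normalized by sqrt(H(a) H(b))."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.shape[0]
    ua, ub = np.unique(a), np.unique(b)
    joint = np.zeros((ua.size, ub.size))
    for i, va in enumerate(ua):
        for j, vb in enumerate(ub):
            joint[i, j] = np.sum((a == va) & (b == vb)) / n
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for i in range(ua.size):
        for j in range(ub.size):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log(joint[i, j] / (pa[i] * pb[j]))
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    return mi / np.sqrt(ha * hb)
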