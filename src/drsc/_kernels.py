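"""Sequential single-site lattice kernels (numba-compiled).

Both the ICM label sweep and the Potts Gibbs sampler visit spots one at a
time in ascending index order, reading the *current* labels of the
neighborhood at each visit — the semantics of coordinate ascent / single-site
Gibbs.  The graph is passed as CSR ``(indptr, indices)`` arrays; labels are
0-based here and converted at the public boundary.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def icm_kernel(loglik, beta, indptr, indices, y, max_sweeps):
    """Coordinate-ascent label sweeps.

    Each site is set to ``argmax_k loglik[i, k] + beta * (#neighbors with
    label k)``, ties broken by the smallest k; full sweeps repeat until no
    label changes or ``max_sweeps`` is hit.  Returns the number of sweeps
    actually performed.
    """
    n, K = loglik.shape
    counts = np.zeros(K, dtype=np.float64)
    sweeps_done = 0
    for _ in range(max_sweeps):
        changed = 0
        for i in range(n):
            for k in range(K):
                counts[k] = 0.0
            for jj in range(indptr[i], indptr[i + 1]):
                counts[y[indices[jj]]] += 1.0
            best_k = 0
            best_v = loglik[i, 0] + beta * counts[0]
            for k in range(1, K):
                v = loglik[i, k] + beta * counts[k]
                if v > best_v:  # strict: ties keep the smaller k
                    best_v = v
                    best_k = k
            if best_k != y[i]:
                y[i] = best_k
                changed += 1
        sweeps_done += 1
        if changed == 0:
            break
    return sweeps_done


@njit(cache=False)
def gibbs_potts_kernel(beta, indptr, indices, y, K, unif, history):
    """Single-site Gibbs sampler for the K-state Potts model.

    ``unif`` is a pre-generated (sweeps, n) array of uniforms (one per site
    visit) so all randomness is controlled by the caller's generator.
    ``history[s]`` receives the label field after sweep ``s``.
    """
    sweeps, n = unif.shape
    w = np.empty(K, dtype=np.float64)
    counts = np.empty(K, dtype=np.float64)
    for s in range(sweeps):
        for i in range(n):
            for k in range(K):
                counts[k] = 0.0
            for jj in range(indptr[i], indptr[i + 1]):
                counts[y[indices[jj]]] += 1.0
            cmax = counts[0]
            for k in range(1, K):
                if counts[k] > cmax:
                    cmax = counts[k]
            total = 0.0
            for k in range(K):
                w[k] = np.exp(beta * (counts[k] - cmax))
                total += w[k]
            u = unif[s, i] * total
            acc = 0.0
            pick = K - 1
            for k in range(K):
                acc += w[k]
                if u < acc:
                    pick = k
                    break
            y[i] = pick
        for i in range(n):
            history[s, i] = y[i]
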