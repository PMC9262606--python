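"""Neighbor-graph construction for lattices, hexagonal and irregular layouts.

The spatial prior couples each spot to its neighborhood N_i.  For array-based
platforms (square lattices) the neighborhood follows from index arithmetic;
for hexagonal (Visium-like) or irregular bead layouts it is derived from the
2-D coordinates, treated as continuous Euclidean positions in input units.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .types import NeighborGraph

logger = logging.getLogger(__name__)


def build_lattice_neighbors(rows: int, cols: int, connectivity: int = 4) -> NeighborGraph:
    """4- or 8-connected graph on a rows x cols lattice, spots row-major.

    Interior spots get 4 (resp. 8) neighbors; edges and corners fewer.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r, c = r.ravel(), c.ravel()
    idx = r * cols + c
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    src, dst = [], []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        src.append(idx[ok])
        dst.append((rr * cols + cc)[ok])
    src = np.concatenate(src) if src else np.array([], dtype=int)
    dst = np.concatenate(dst) if dst else np.array([], dtype=int)
    n = rows * cols
    adj = sp.coo_matrix(
        (np.ones(2 * src.size), (np.r_[src, dst], np.r_[dst, src])), shape=(n, n)
    ).tocsr()
    coords = np.column_stack([c.astype(float), r.astype(float)])
    return NeighborGraph(adj, coords)


def build_coord_neighbors(
    coords: np.ndarray,
    method: str = "knn",
    k: int = 6,
    r: float | None = None,
) -> NeighborGraph:
    """Neighbor graph from 2-D coordinates.

    ``knn``: mutualized k-nearest-neighbor graph, symmetrized (an edge is
    kept iff either endpoint selects the other).  ``radius``: all pairs at
    Euclidean distance <= r.  ``hex``: radius rule with r = 1.2x the minimal
    nonzero pairwise distance, which yields the 6 interior neighbors of a
    regular hexagonal grid.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    n = coords.shape[0]
    if coords.shape[1] != 2:
        raise ValueError("coords must be n x 2")
    tree = cKDTree(coords)
    if n > 1:
        d_min, _ = tree.query(coords, k=2)
        min_nonzero = d_min[:, 1][d_min[:, 1] > 0]
        n_dup = int((d_min[:, 1] == 0).sum())
        if n_dup:
            logger.warning("%d spots share coordinates with another spot", n_dup)
        if min_nonzero.size == 0:
            raise ValueError("all coordinates coincide; no neighbor scale exists")
    if method == "knn":
        if k < 1:
            raise ValueError("k must be >= 1")
        kk = min(k + 1, n)
        _, nb = tree.query(coords, k=kk)
        nb = np.atleast_2d(nb)
        src = np.repeat(np.arange(n), nb.shape[1] - 1)
        dst = nb[:, 1:].ravel()
    elif method in ("radius", "hex"):
        if method == "hex":
            r = 1.2 * float(min_nonzero.min()) if n > 1 else 1.0
        if r is None or r <= 0:
            raise ValueError("radius must be positive")
        pairs = tree.query_pairs(r, output_type="ndarray")
        src, dst = pairs[:, 0], pairs[:, 1]
    else:
        raise ValueError(f"unknown method {method!r}")
    adj = sp.coo_matrix(
        (np.ones(2 * src.size), (np.r_[src, dst], np.r_[dst, src])), shape=(n, n)
    ).tocsr()
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj.data = np.ones_like(adj.data)  # de-duplicate parallel edges
    return NeighborGraph(adj, coords)
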