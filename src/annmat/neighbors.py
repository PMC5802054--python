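"""Neighborhood graph engine.

Pairwise Euclidean distances are computed block-by-block via the expansion
``d(q, x)² = ‖q‖² + ‖x‖² − 2 q·x`` so that the dominant cost is one matrix
multiplication per row block and peak memory stays O(block_size × n).  From the
k-nearest-neighbor distances an adaptive Gaussian kernel builds symmetric
connectivities, and from those a row-stochastic transition operator (optionally
density-normalized) that every downstream tool — diffusion maps, pseudotime,
Louvain, graph layout — reuses without recomputing distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

#: default rows per distance block; chosen so a block of a 100k-cell matrix
#: stays well under a gigabyte
DEFAULT_BLOCK_SIZE = 1024


@dataclass
class NeighborGraph:
    """kNN distances, Gaussian connectivities and the random-walk operator."""

    n_obs: int
    k: int
    distances: sp.csr_matrix | None = None  # k stored entries per row, self excluded
    connectivities: sp.csr_matrix | None = None  # symmetric W, entries in (0, 1]
    sigmas: np.ndarray | None = None  # per-node kernel width
    transition: sp.csr_matrix | None = None  # row-stochastic T
    transition_sym: sp.csr_matrix | None = None  # D^{-1/2} K̃ D^{-1/2}, same spectrum
    degree_norm: np.ndarray | None = None  # density normalizer z_i = Σ_j W_ij
    params: dict = field(default_factory=dict)

    def to_uns(self) -> dict:
        out = {"n_obs": self.n_obs, "k": self.k, "params": dict(self.params)}
        for key in ("distances", "connectivities", "transition", "transition_sym"):
            m = getattr(self, key)
            if m is not None:
                out[key] = m
        for key in ("sigmas", "degree_norm"):
            v = getattr(self, key)
            if v is not None:
                out[key] = v
        return out

    @classmethod
    def from_uns(cls, d: dict) -> "NeighborGraph":
        g = cls(n_obs=int(d["n_obs"]), k=int(d["k"]), params=dict(d.get("params", {})))
        for key in ("distances", "connectivities", "transition", "transition_sym"):
            if key in d:
                setattr(g, key, sp.csr_matrix(d[key]))
        for key in ("sigmas", "degree_norm"):
            if key in d:
                setattr(g, key, np.asarray(d[key]))
        return g


def blocked_pairwise_distances(X, block_size: int = DEFAULT_BLOCK_SIZE):
    """Yield ``(start, stop, D_block)`` with ``D_block[i - start, j] = ‖x_i − x_j‖``.

    Concatenating the blocks gives the full n × n Euclidean distance matrix;
    negative round-off under the square root is clamped to zero.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be 2-D with at least one feature")
    if block_size < 1:
        raise ValueError("block_size must be ≥ 1")
    n = X.shape[0]
    sq = np.einsum("ij,ij->i", X, X)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        Q = X[start:stop]
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (Q @ X.T)
        np.maximum(d2, 0.0, out=d2)
        yield start, stop, np.sqrt(d2, out=d2)


def _knn_block(d_block: np.ndarray, start: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-row k nearest (self excluded); ties broken by lower column index."""
    b, n = d_block.shape
    rows = np.arange(b)
    d_block[rows, start + rows] = np.inf  # mask self
    if n <= 4096:
        # full stable argsort: exact lexicographic (distance, index) tie-break
        order = np.argsort(d_block, axis=1, kind="stable")[:, :k]
    else:
        cand = np.argpartition(d_block, kth=k, axis=1)[:, : k + 1]
        cd = np.take_along_axis(d_block, cand, axis=1)
        # stable sort candidates by distance, then index
        local = np.lexsort((cand, cd), axis=1)[:, :k]
        order = np.take_along_axis(cand, local, axis=1)
    dist = np.take_along_axis(d_block, order, axis=1)
    return order, dist


def knn_graph(X, k: int, block_size: int = DEFAULT_BLOCK_SIZE) -> NeighborGraph:
    """Exact kNN graph: per row the k smallest Euclidean distances, self excluded.

    Deterministic: ties are broken toward the lower index, and the result is
    independent of ``block_size``.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 ≤ k ≤ n−1 = {n - 1}, got {k}")
    idx = np.empty((n, k), dtype=np.int64)
    dst = np.empty((n, k), dtype=np.float64)
    for start, stop, d_block in blocked_pairwise_distances(X, block_size):
        order, dist = _knn_block(d_block, start, k)
        idx[start:stop] = order
        dst[start:stop] = dist
    indptr = np.arange(0, n * k + 1, k)
    distances = sp.csr_matrix((dst.ravel(), idx.ravel(), indptr), shape=(n, n))
    return NeighborGraph(
        n_obs=n,
        k=k,
        distances=distances,
        params={"metric": "euclidean", "block_size": block_size},
    )


def gaussian_connectivities(g: NeighborGraph) -> NeighborGraph:
    """Adaptive Gaussian kernel weights on the kNN graph.

    σ_i is the distance to the k-th nearest neighbor (local scaling); each
    stored pair gets W_ij = exp(−d_ij² / (σ_i² + σ_j²)); W is symmetrized by
    elementwise max (union of neighborhoods) with zero diagonal.
    """
    if g.distances is None:
        raise ValueError("kNN distances missing; run knn_graph first")
    D = g.distances
    n = g.n_obs
    sigmas = np.asarray(D.max(axis=1).todense()).ravel()
    zero = sigmas == 0
    if zero.any():
        positive = sigmas[~zero]
        fill = positive.min() if positive.size else 1.0
        warnings.warn(
            f"{int(zero.sum())} node(s) have σ=0 (duplicate points saturate the "
            f"neighbor list); σ set to {fill:.3g}",
            UserWarning,
        )
        sigmas = np.where(zero, fill, sigmas)
    C = D.tocoo()
    denom = sigmas[C.row] ** 2 + sigmas[C.col] ** 2
    w = np.exp(-(C.data**2) / denom)
    W = sp.csr_matrix((w, (C.row, C.col)), shape=(n, n))
    W = W.maximum(W.T)
    W.setdiag(0)
    W.eliminate_zeros()
    g.connectivities = W
    g.sigmas = sigmas
    return g


def transition_matrix(g: NeighborGraph, density_normalize: bool = True) -> NeighborGraph:
    """Row-stochastic random-walk operator T (and its symmetric conjugate).

    With density normalization the kernel is first corrected for sampling
    density, K̃_ij = W_ij/(z_i z_j) with z_i = Σ_j W_ij, before row
    normalization — this removes the bias of cell density on the diffusion
    geometry.  ``transition_sym = D^{−1/2} K̃ D^{−1/2}`` shares T's spectrum and
    is what the eigensolver consumes.
    """
    if g.connectivities is None:
        raise ValueError("connectivities missing; run gaussian_connectivities first")
    W = g.connectivities
    z = np.asarray(W.sum(axis=1)).ravel()
    if (z == 0).any():
        raise ValueError(
            f"{int((z == 0).sum())} isolated node(s); increase k so the graph connects"
        )
    if density_normalize:
        inv_z = sp.diags(1.0 / z)
        K = inv_z @ W @ inv_z
    else:
        K = W.copy()
    q = np.asarray(K.sum(axis=1)).ravel()
    g.transition = sp.diags(1.0 / q) @ K
    inv_sqrt_q = sp.diags(1.0 / np.sqrt(q))
    g.transition_sym = (inv_sqrt_q @ K @ inv_sqrt_q).tocsr()
    g.degree_norm = z
    g.params["density_normalize"] = bool(density_normalize)
    return g


def neighbors(X, k: int = 15, block_size: int = DEFAULT_BLOCK_SIZE,
              density_normalize: bool = True) -> NeighborGraph:
    """Convenience: kNN graph → Gaussian connectivities → transition operator."""
    g = knn_graph(X, k=k, block_size=block_size)
    gaussian_connectivities(g)
    transition_matrix(g, density_normalize=density_normalize)
    return g
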