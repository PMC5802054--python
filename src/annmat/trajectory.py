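"""Trajectory inference: diffusion maps, diffusion pseudotime, branching, layout.

The random-walk operator T from the neighbor graph is diagonalized through its
symmetric conjugate T_sym = D^{−1/2} K̃ D^{−1/2}; eigenvectors are
back-transformed by D^{−1/2}, so the leading component ψ_0 (eigenvalue 1) is
constant.  Diffusion pseudotime accumulates the random walk over all path
lengths: with orthonormal eigenvectors v_i of T_sym and a_i = λ_i/(1−λ_i),

    dpt(x, y)² = Σ_{i≥1} a_i² (v_i(x) − v_i(y))²,

which equals the Euclidean distance between rows x and y of the accumulated
matrix M = (I − (T_sym − v_0 v_0ᵀ))⁻¹ − I.  Pseudotime is dpt to a chosen root
cell, rescaled to [0, 1].  Branching is detected by ordering cells from
opposite tips and splitting where the two orderings cease to be
anti-correlated (a running Kendall-correlation criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import kendalltau

from .neighbors import NeighborGraph

#: eigenvalues within EPS of 1 beyond the trivial one are excluded from dpt
EPS_EIGENVALUE = 1e-10


@dataclass
class DiffusionResult:
    """Eigenpairs of the transition operator.

    ``components`` are the back-transformed eigenvectors ψ_i = D^{−1/2} v_i
    (orthonormal under the stationary-measure inner product); ``components_sym``
    are the orthonormal v_i of the symmetric conjugate, used by dpt.
    """

    eigenvalues: np.ndarray  # descending, λ_0 = 1
    components: np.ndarray  # n_obs × (m+1)
    components_sym: np.ndarray  # n_obs × (m+1)


@dataclass
class DptResult:
    root: int
    pseudotime: np.ndarray | None = None  # in [0, 1]
    segments: np.ndarray | None = None  # integer branch labels, trunk = 0
    dpt_to_root: np.ndarray | None = None  # raw dpt distances


@dataclass
class LayoutResult:
    coords: np.ndarray  # n_obs × 2, finite
    iterations: int
    seed: int


def _fix_signs(V: np.ndarray) -> np.ndarray:
    flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    return V


def diffusion_map(g: NeighborGraph, n_comps: int = 10) -> DiffusionResult:
    """Top ``n_comps``+1 eigenpairs of the transition operator.

    Solved on the symmetric conjugate (stable, orthonormal basis) and
    back-transformed; eigenvalues sorted descending with the deterministic
    sign convention (largest-magnitude entry positive).
    """
    if g.transition_sym is None:
        raise ValueError("transition matrix missing; run transition_matrix first")
    Ts = g.transition_sym
    n = g.n_obs
    k = n_comps + 1
    if k >= n - 1:
        evals, evecs = np.linalg.eigh(Ts.toarray())
        evals, evecs = evals[::-1], evecs[:, ::-1]
        evals, evecs = evals[: min(k, n)], evecs[:, : min(k, n)]
    else:
        try:
            evals, evecs = sp.linalg.eigsh(Ts, k=k, which="LA", v0=np.full(n, 1.0 / np.sqrt(n)))
        except sp.linalg.ArpackNoConvergence as e:
            raise RuntimeError(
                "eigensolver did not converge; try a larger k for the neighbor "
                "graph or fewer diffusion components"
            ) from e
        order = np.argsort(-evals)
        evals, evecs = evals[order], evecs[:, order]
    evecs = _fix_signs(np.ascontiguousarray(evecs))
    # back-transform ψ = D^{-1/2} v; D holds the (density-normalized) kernel degrees
    W = g.connectivities
    z = np.asarray(W.sum(axis=1)).ravel()
    if g.params.get("density_normalize", True):
        inv_z = sp.diags(1.0 / z)
        K = inv_z @ W @ inv_z
        q = np.asarray(K.sum(axis=1)).ravel()
    else:
        q = z
    psi = evecs / np.sqrt(q)[:, None]
    return DiffusionResult(eigenvalues=evals, components=psi, components_sym=evecs)


def _dpt_weights(dm: DiffusionResult) -> tuple[np.ndarray, np.ndarray]:
    """Indices and weights a_i = λ_i/(1−λ_i) of usable non-trivial components."""
    lam = dm.eigenvalues
    use = np.flatnonzero(lam[1:] < 1.0 - EPS_EIGENVALUE) + 1
    n_excluded = (lam.size - 1) - use.size
    if n_excluded:
        warnings.warn(
            f"{n_excluded} non-trivial component(s) with λ ≥ 1−ε excluded from dpt "
            "(disconnected or near-invariant direction)",
            UserWarning,
        )
    return use, lam[use] / (1.0 - lam[use])


def dpt_distances(dm: DiffusionResult, x: int, y: int) -> float:
    """Diffusion-pseudotime distance between cells ``x`` and ``y``."""
    use, a = _dpt_weights(dm)
    V = dm.components_sym
    diff = a * (V[x, use] - V[y, use])
    return float(np.sqrt(np.sum(diff**2)))


def _dpt_from(dm: DiffusionResult, root: int) -> np.ndarray:
    """Vectorized dpt(root, ·) over all cells."""
    use, a = _dpt_weights(dm)
    V = dm.components_sym
    diff = (V[:, use] - V[root, use]) * a
    return np.sqrt(np.einsum("ij,ij->i", diff, diff))


def dpt_pseudotime(dm: DiffusionResult, root: int) -> DptResult:
    """Pseudotime = dpt distance to the root cell, rescaled to [0, 1]."""
    n = dm.components_sym.shape[0]
    if not 0 <= root < n:
        raise ValueError(f"root index {root} out of range [0, {n})")
    d = _dpt_from(dm, root)
    dmax = d.max()
    pt = d / dmax if dmax > 0 else d
    return DptResult(root=root, pseudotime=pt, dpt_to_root=d)


def _kendall_tau_split(a: np.ndarray, b: np.ndarray, min_seg: int = 5) -> int:
    """Index i maximizing tau(a[:i], b[:i]) − tau(a[i:], b[i:]).

    Along a branch the two tip-distance orderings agree (positive correlation);
    past the branch point they disagree — the split sits at the change point.
    """
    n = a.size
    if n < 2 * min_seg:
        return n
    best_i, best = min_seg, -np.inf
    for i in range(min_seg, n - min_seg + 1):
        t1 = kendalltau(a[:i], b[:i]).statistic
        t2 = kendalltau(a[i:], b[i:]).statistic
        t1 = 0.0 if np.isnan(t1) else t1
        t2 = 0.0 if np.isnan(t2) else t2
        score = t1 - t2
        if score > best + 1e-12:
            best, best_i = score, i
    return best_i


def _branch_from_tip(d_tip: np.ndarray, d_other1: np.ndarray, d_other2: np.ndarray) -> np.ndarray:
    """Cells belonging to a tip's branch: those before the correlation switch
    when ordered by distance from the tip."""
    order = np.argsort(d_tip, kind="stable")
    i = _kendall_tau_split(d_other1[order], d_other2[order])
    return order[:i]


def detect_branching(dm: DiffusionResult, root: int, n_branchings: int = 1) -> DptResult:
    """Partition cells into trajectory segments by iterative branching splits.

    One split finds the tip μ farthest (in dpt) from the root, the tip ν
    maximizing the summed dpt distance from root and μ, and assigns each of
    the three tips the stretch of cells
    whose orderings from the two other tips remain positively correlated.
    Cells claimed by no branch or by several go to the trunk (segment 0, the
    root's side of the split).  Further splits recurse on the largest segment.
    """
    n = dm.components_sym.shape[0]
    res = dpt_pseudotime(dm, root)
    segments = np.zeros(n, dtype=np.int64)
    if n_branchings <= 0:
        res.segments = segments
        return res
    next_label = 1
    for _ in range(n_branchings):
        # split the largest segment
        labels, counts = np.unique(segments, return_counts=True)
        seg_label = labels[np.argmax(counts)]
        cells = np.flatnonzero(segments == seg_label)
        if cells.size < 10:
            break
        # segment-local root: the member cell nearest the global root in dpt
        d_root_all = _dpt_from(dm, root)
        local_root = cells[np.argmin(d_root_all[cells])]
        d0 = _dpt_from(dm, local_root)[cells]
        mu = cells[np.argmax(d0)]
        d1 = _dpt_from(dm, mu)[cells]
        # third tip: farthest from BOTH ends of the root–μ path, so it lands on
        # the other branch rather than back near the root
        nu = cells[np.argmax(d0 + d1)]
        d2 = _dpt_from(dm, nu)[cells]

        # degeneracy gate: a real branch tip ν lies well off the root–μ path,
        # so d0(ν)+d1(ν) exceeds d(root, μ); on a linear segment it does not
        i_nu = int(np.argmax(d0 + d1))
        d_root_mu = d0[np.argmax(d0)]
        if d0[i_nu] + d1[i_nu] < 1.25 * d_root_mu:
            break  # split degenerates: segment has no branching

        b_root = _branch_from_tip(d0, d1, d2)
        b_mu = _branch_from_tip(d1, d0, d2)
        b_nu = _branch_from_tip(d2, d0, d1)

        claim = np.zeros((cells.size, 3), dtype=bool)
        claim[b_root, 0] = True
        claim[b_mu, 1] = True
        claim[b_nu, 2] = True
        n_claims = claim.sum(axis=1)
        tip_dists = np.column_stack([d0, d1, d2])
        labels3 = np.array([seg_label, next_label, next_label + 1])
        new = np.empty(cells.size, dtype=np.int64)
        # uniquely claimed cells follow their branch; ambiguous cells (claimed
        # by several stretches or by none, i.e. near the fork) go to the tip
        # nearest in dpt — for a symmetric Y that boundary is the fork itself
        nearest = np.argmin(tip_dists, axis=1)
        new[:] = labels3[nearest]
        for which, lab in ((0, seg_label), (1, next_label), (2, next_label + 1)):
            unique = (n_claims == 1) & claim[:, which]
            new[unique] = lab
        segments[cells] = new
        next_label += 2
    # relabel so the trunk (segment containing the root) is 0, rest by size
    root_label = segments[root]
    labels, counts = np.unique(segments, return_counts=True)
    order = [root_label] + [
        l for l in labels[np.argsort(-counts, kind="stable")] if l != root_label
    ]
    remap = {old: i for i, old in enumerate(order)}
    res.segments = np.asarray([remap[s] for s in segments], dtype=np.int64)
    return res


def fr_layout(g: NeighborGraph, iterations: int = 100, seed: int = 0) -> LayoutResult:
    """Classic Fruchterman–Reingold force-directed layout on the connectivities.

    Area = n (unit density) so the optimal edge length is k_opt = 1; attraction
    d²/k_opt on edges scaled by the edge weight, repulsion k_opt²/d between all
    pairs (restricted to a 3·k_opt radius through a uniform grid when
    n > 2000); linear cooling from 0.1·√area.
    """
    if g.connectivities is None or g.n_obs == 0:
        raise ValueError("graph with connectivities required")
    W = g.connectivities.tocoo()
    n = g.n_obs
    area = float(n)
    k_opt = np.sqrt(area / n)  # = 1 by construction; kept explicit
    rng = np.random.default_rng(seed)
    side = np.sqrt(area)
    pos = rng.uniform(0.0, side, size=(n, 2))
    t0 = 0.1 * side
    upper = W.row < W.col  # each undirected edge once
    row, col, w = W.row[upper], W.col[upper], W.data[upper]
    use_grid = n > 2000
    cutoff = 3.0 * k_opt
    for it in range(iterations):
        disp = np.zeros((n, 2))
        if not use_grid:
            delta = pos[:, None, :] - pos[None, :, :]
            dist = np.sqrt((delta**2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            dist = np.maximum(dist, 1e-9)
            disp += (delta / dist[..., None] * (k_opt**2 / dist)[..., None]).sum(axis=1)
        else:
            # bucket nodes on a grid of cell size = cutoff; repel within the
            # 3×3 neighborhood of cells only
            keys = np.floor(pos / cutoff).astype(np.int64)
            buckets: dict[tuple[int, int], list[int]] = {}
            for i, key in enumerate(map(tuple, keys)):
                buckets.setdefault(key, []).append(i)
            for (cx, cy), members in buckets.items():
                neigh = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        neigh.extend(buckets.get((cx + dx, cy + dy), ()))
                P, Q = pos[members], pos[neigh]
                delta = P[:, None, :] - Q[None, :, :]
                dist = np.sqrt((delta**2).sum(-1))
                mask = (dist < cutoff) & (dist > 0)
                dist = np.maximum(dist, 1e-9)
                contrib = delta / dist[..., None] * (k_opt**2 / dist)[..., None]
                contrib[~mask] = 0.0
                disp[members] += contrib.sum(axis=1)
        # attraction along edges, weighted
        delta = pos[row] - pos[col]
        dist = np.maximum(np.sqrt((delta**2).sum(-1)), 1e-9)
        f = (dist**2 / k_opt) * w
        vec = delta / dist[:, None] * f[:, None]
        np.subtract.at(disp, row, vec)
        np.add.at(disp, col, vec)
        # cap movement by the cooling temperature
        t = t0 * (1.0 - it / iterations)
        length = np.maximum(np.sqrt((disp**2).sum(-1)), 1e-9)
        pos += disp / length[:, None] * np.minimum(length, t)[:, None]
    if not np.isfinite(pos).all():
        raise RuntimeError("layout diverged to non-finite coordinates")
    return LayoutResult(coords=pos, iterations=iterations, seed=seed)


def accumulated_transition_matrix(g: NeighborGraph) -> np.ndarray:
    """Dense M = (I − (T_sym − v_0 v_0ᵀ))⁻¹ − I (small graphs only).

    The Euclidean distance between rows of M is the dpt distance; used as the
    explicit cross-check of the spectral formula.
    """
    Ts = g.transition_sym.toarray()
    n = Ts.shape[0]
    evals, evecs = np.linalg.eigh(Ts)
    v0 = evecs[:, -1:]
    M = np.linalg.inv(np.eye(n) - (Ts - v0 @ v0.T)) - np.eye(n)
    return M
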