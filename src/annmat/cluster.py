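"""Louvain community detection on the neighbor graph and marker-gene ranking.

Louvain maximizes the (resolution-scaled) Newman–Girvan modularity

    Q = Σ_c [ e_c / m_w − γ (d_c / (2 m_w))² ]

with e_c the within-community edge weight, d_c the community degree sum and
m_w the total edge weight, by alternating greedy local moves with graph
aggregation.  Marker genes are ranked per cluster against all other cells with
a Welch t-test or a Wilcoxon rank-sum z (normal approximation, tie-corrected),
Benjamini–Hochberg-adjusted within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .core import AnnMatrix
from .neighbors import NeighborGraph


@dataclass
class ClusterResult:
    labels: np.ndarray  # contiguous ints from 0, ordered by decreasing size
    modularity: float
    resolution: float
    seed: int


@dataclass
class RankResult:
    """Per-group marker ranking: parallel arrays sorted by descending score."""

    groups: list[str]
    names: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    pvals: dict[str, np.ndarray] = field(default_factory=dict)
    pvals_adj: dict[str, np.ndarray] = field(default_factory=dict)
    log2fc: dict[str, np.ndarray] = field(default_factory=dict)

    def to_uns(self) -> dict:
        out: dict = {"groups": list(self.groups)}
        for g in self.groups:
            out[g] = {
                "names": self.names[g],
                "scores": self.scores[g],
                "pvals": self.pvals[g],
                "pvals_adj": self.pvals_adj[g],
                "log2fc": self.log2fc[g],
            }
        return out


def modularity(W, labels, resolution: float = 1.0) -> float:
    """Modularity Q of a partition of the symmetric weighted graph ``W``."""
    W = sp.csr_matrix(W)
    labels = np.asarray(labels)
    if labels.shape[0] != W.shape[0]:
        raise ValueError(
            f"labels length {labels.shape[0]} != number of nodes {W.shape[0]}"
        )
    total = W.sum()  # = 2 m_w for a symmetric matrix
    if total == 0:
        return 0.0
    degrees = np.asarray(W.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        in_c = labels == c
        e_c = W[in_c][:, in_c].sum() / 2.0  # within-community edge weight
        d_c = degrees[in_c].sum()
        q += e_c / (total / 2.0) - resolution * (d_c / total) ** 2
    return float(q)


def _louvain_local_move(
    indptr, indices, data, self_loops, labels, total, resolution, rng
):
    """One local-moving phase; returns True if any node moved."""
    n = labels.shape[0]
    strength = self_loops + np.asarray(
        [data[indptr[i] : indptr[i + 1]].sum() for i in range(n)]
    )
    comm_tot = np.zeros(n)
    np.add.at(comm_tot, labels, strength)
    improved_any = False
    for _ in range(100):  # sweeps until stable
        moved = 0
        for i in rng.permutation(n):
            ci = labels[i]
            lo, hi = indptr[i], indptr[i + 1]
            neigh, w = indices[lo:hi], data[lo:hi]
            links: dict[int, float] = {}
            for j, wij in zip(neigh, w):
                if j != i:
                    cj = labels[j]
                    links[cj] = links.get(cj, 0.0) + wij
            ki = strength[i]
            comm_tot[ci] -= ki
            base = links.get(ci, 0.0) - resolution * ki * comm_tot[ci] / total
            best_c, best_gain = ci, 0.0
            for c, k_in in links.items():
                if c == ci:
                    continue
                gain = (k_in - resolution * ki * comm_tot[c] / total) - base
                if gain > best_gain + 1e-12 or (
                    gain > best_gain - 1e-12 and gain > 0 and c < best_c
                ):
                    best_c, best_gain = c, gain
            comm_tot[best_c] += ki
            if best_c != ci:
                labels[i] = best_c
                moved += 1
        if moved:
            improved_any = True
        else:
            break
    return improved_any


def louvain_cluster(
    g: NeighborGraph | sp.spmatrix,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterResult:
    """Two-phase Louvain clustering of the neighbor graph.

    Local moving (seeded node order) alternates with community aggregation
    until the modularity stops improving; labels are relabeled by decreasing
    community size.
    """
    W = g.connectivities if isinstance(g, NeighborGraph) else sp.csr_matrix(g)
    if W is None or W.shape[0] == 0:
        raise ValueError("non-empty graph with connectivities required")
    W = sp.csr_matrix(W)
    n = W.shape[0]
    total = float(W.sum())  # 2 m_w
    rng = np.random.default_rng(seed)

    membership = np.arange(n)  # node -> community on the original graph
    if total == 0:
        labels = membership
    else:
        cur = W.copy()
        cur.setdiag(0)
        cur.eliminate_zeros()
        self_loops = np.zeros(n)
        while True:
            m = cur.shape[0]
            labels = np.arange(m)
            improved = _louvain_local_move(
                cur.indptr, cur.indices, cur.data, self_loops, labels, total,
                resolution, rng,
            )
            if not improved:
                break
            # aggregate communities into a supergraph
            uniq, labels = np.unique(labels, return_inverse=True)
            m2 = uniq.shape[0]
            membership = labels[membership]
            S = sp.csr_matrix(
                (np.ones(m), (np.arange(m), labels)), shape=(m, m2)
            )
            agg = (S.T @ (cur + sp.diags(self_loops)) @ S).tocsr()
            self_loops = agg.diagonal().copy()
            agg.setdiag(0)
            agg.eliminate_zeros()
            if m2 == m:
                break
            cur = agg
        labels = membership

    # contiguous ids ordered by decreasing community size (ties: first seen)
    uniq, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    final = remap[inverse]
    q = modularity(W, final, resolution)
    return ClusterResult(labels=final, modularity=q, resolution=resolution, seed=seed)


def brute_force_best_partition(W, resolution: float = 1.0):
    """Exhaustive modularity maximization over all set partitions (n ≤ 10).

    Exponential-cost reference used to validate Louvain on tiny graphs.
    """
    W = sp.csr_matrix(W)
    n = W.shape[0]
    if n > 10:
        raise ValueError("brute force is limited to n ≤ 10 nodes")

    A = W.toarray()
    np.fill_diagonal(A, 0.0)
    total = A.sum()  # 2 m_w
    degrees = A.sum(axis=1)
    best_q, best_labels = -np.inf, None

    def partitions(seq):
        if not seq:
            yield []
            return
        first, rest = seq[0], seq[1:]
        for smaller in partitions(rest):
            for i, subset in enumerate(smaller):
                yield smaller[:i] + [subset + [first]] + smaller[i + 1 :]
            yield [[first]] + smaller

    for part in partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        if total == 0:
            q = 0.0
        else:
            same = labels[:, None] == labels[None, :]
            e_within = (A * same).sum()  # counts both directions
            d_c = np.bincount(labels, weights=degrees)
            q = e_within / total - resolution * ((d_c / total) ** 2).sum()
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


# -- marker-gene ranking -------------------------------------------------------


def _group_mean_var(X, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    n = int(mask.sum())
    Xg = X[mask]
    if sp.issparse(Xg):
        mean = np.asarray(Xg.mean(axis=0)).ravel()
        sq = np.asarray(Xg.multiply(Xg).mean(axis=0)).ravel()
    else:
        mean = Xg.mean(axis=0)
        sq = (np.asarray(Xg) ** 2).mean(axis=0)
    var = np.maximum(sq - mean**2, 0.0) * (n / max(n - 1, 1))
    return mean, var, n


def _welch(mean1, var1, n1, mean2, var2, n2):
    se2 = var1 / n1 + var2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, (mean1 - mean2) / np.sqrt(se2), 0.0)
        df = np.where(
            se2 > 0,
            se2**2
            / (
                (var1 / n1) ** 2 / max(n1 - 1, 1)
                + (var2 / n2) ** 2 / max(n2 - 1, 1)
                + 1e-300
            ),
            1.0,
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def _wilcoxon_z(X, mask: np.ndarray) -> np.ndarray:
    """Tie-corrected rank-sum z per gene (normal approximation, no continuity)."""
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X)
    n = Xd.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    ranks = stats.rankdata(Xd, axis=0)
    r1 = ranks[mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie correction: Σ(t³ − t) over tied groups, per gene
    tie_term = np.zeros(Xd.shape[1])
    for j in range(Xd.shape[1]):
        _, counts = np.unique(Xd[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0, (r1 - mu) / np.sqrt(sigma2), 0.0)
    return z


def rank_genes_groups(
    a: AnnMatrix,
    group_col: str,
    method: str = "ttest",
    n_genes: int | None = None,
) -> RankResult:
    """Rank genes for each group against the rest of the cells.

    ``ttest`` uses the Welch statistic with Welch–Satterthwaite degrees of
    freedom; ``wilcoxon`` the tie-corrected rank-sum z.  P-values are two-sided
    and Benjamini–Hochberg-adjusted across genes within each group.  Log2 fold
    changes are computed on expm1-backtransformed group means with a 1e-9
    pseudocount.  Groups with fewer than two cells are skipped with a warning.
    """
    if method not in ("ttest", "wilcoxon"):
        raise ValueError(f"method must be 'ttest' or 'wilcoxon', got {method!r}")
    if group_col not in a.obs.columns:
        raise KeyError(f"obs column {group_col!r} not found")
    if not a.uns.get("log1p"):
        warnings.warn(
            "X does not appear to be log1p-transformed; statistics assume log scale",
            UserWarning,
        )
    X = a.to_memory().X
    groups_series = a.obs[group_col]
    if not isinstance(groups_series.dtype, pd.CategoricalDtype):
        groups_series = groups_series.astype("category")
    var_names = np.asarray(a.var_names, dtype=object)
    n_genes = a.n_var if n_genes is None else min(n_genes, a.n_var)

    res = RankResult(groups=[])
    for grp in groups_series.cat.categories:
        mask = (groups_series == grp).to_numpy()
        if mask.sum() < 2:
            warnings.warn(f"group {grp!r} has < 2 cells; skipped", UserWarning)
            continue
        mean1, var1, n1 = _group_mean_var(X, mask)
        mean2, var2, n2 = _group_mean_var(X, ~mask)
        if method == "ttest":
            score, p = _welch(mean1, var1, n1, mean2, var2, n2)
        else:
            score = _wilcoxon_z(X, mask)
            p = 2.0 * stats.norm.sf(np.abs(score))
        p = np.clip(p, 0.0, 1.0)
        p_adj = stats.false_discovery_control(p, method="bh")
        # back-transform to the count scale; scaled data can yield negative
        # means whose expm1 is ≤ −1, so clip at zero before the pseudocount
        lfc = np.log2(
            (np.maximum(np.expm1(mean1), 0.0) + 1e-9)
            / (np.maximum(np.expm1(mean2), 0.0) + 1e-9)
        )
        order = np.lexsort((np.arange(score.size), -score))[:n_genes]
        key = str(grp)
        res.groups.append(key)
        res.names[key] = var_names[order]
        res.scores[key] = score[order]
        res.pvals[key] = p[order]
        res.pvals_adj[key] = p_adj[order]
        res.log2fc[key] = lfc[order]
    return res
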