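"""Synthetic single-cell fixtures with ground truth.

Two generators make every pipeline stage testable without external data:

* :func:`generate_mixture` — cells from well-separated Gaussian clusters in a
  10-dimensional latent space (centers at pairwise distance δ in units of the
  unit within-cluster standard deviation); ``obs['true_cluster']`` records the
  ground truth.
* :func:`generate_branching` — cells along a Y-shaped curve (trunk plus two
  branches, uniform time in [0, 1]) with the same count model;
  ``obs['true_time']`` and ``obs['true_branch']`` record the ground truth
  (trunk = branch 0).

Count model: gene means log-linear in the latent program activities (log-normal
baselines × sparse signed log-fold factors), negative-binomial sampling via the
gamma–Poisson mixture with fixed dispersion 0.1, and log-normal library-size
variation (sd 0.3), so that normalization and variable-gene selection are
non-trivially exercised.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import AnnMatrix

LATENT_DIM = 10


@dataclass
class FixtureSpec:
    kind: str  # "mixture" | "branching"
    n_cells: int = 600
    n_genes: int = 300
    n_clusters: int = 3
    n_branches: int = 2
    separation: float = 8.0
    nb_dispersion: float = 0.1
    libsize_sigma: float = 0.3
    mean_total: float = 5000.0
    lfc_sd: float = 0.15
    lfc_density: float = 0.3
    sparse: bool = False  # emit CSR counts, generated in row blocks
    seed: int = 0


def _counts_from_latent(
    z: np.ndarray, n_genes: int, rng: np.random.Generator, spec: FixtureSpec
) -> np.ndarray:
    """Map latent program activities to overdispersed counts.

    Gene means are log-linear in the latent coordinates: each gene draws a
    log-normal baseline and a sparse vector of signed log-fold factors (30% of
    latent dimensions active, sd 0.15 per unit of latent activity), so latent
    programs regulate genes up *and* down and total counts stay comparable
    across states — as in real data, where cell identity is compositional
    rather than a library-size effect.  Per-cell log-normal size factors and a
    gamma–Poisson (negative binomial, dispersion α) sampler add the technical
    and biological count noise.
    """
    n, d = z.shape
    lfc = rng.normal(0.0, spec.lfc_sd, size=(d, n_genes))
    lfc *= rng.random(size=lfc.shape) < spec.lfc_density
    base = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    log_base = np.log(base)
    size_factors = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n))
    alpha = spec.nb_dispersion

    # rescale to the target mean library size (estimated on a cell subsample
    # when n is large, so the full mean matrix need never be materialized)
    probe = z if n <= 20000 else z[:: max(1, n // 10000)]
    scale = spec.mean_total / np.exp(log_base + probe @ lfc).sum(axis=1).mean()

    def block_counts(rows: slice) -> np.ndarray:
        mu = np.exp(log_base + z[rows] @ lfc) * scale * size_factors[rows, None]
        # NB(mean, dispersion α): gamma(1/α, α·mean) mixed with Poisson
        lam = rng.gamma(1.0 / alpha, alpha * mu)
        return rng.poisson(lam).astype(np.float64)

    if not spec.sparse:
        return block_counts(slice(None))
    step = max(1, 10_000_000 // n_genes)
    blocks = [
        sp.csr_matrix(block_counts(slice(s, min(s + step, n))))
        for s in range(0, n, step)
    ]
    return sp.vstack(blocks, format="csr")


def generate_mixture(spec: FixtureSpec | None = None, **kwargs) -> AnnMatrix:
    """Gaussian-mixture fixture with ``obs['true_cluster']`` ground truth."""
    spec = spec or FixtureSpec(kind="mixture", **kwargs)
    if spec.separation <= 0:
        raise ValueError(f"separation must be positive, got {spec.separation}")
    if spec.n_clusters > LATENT_DIM:
        raise ValueError(f"at most {LATENT_DIM} clusters supported")
    rng = np.random.default_rng(spec.seed)
    # simplex construction: centers δ/√2 · e_i are pairwise exactly δ apart
    centers = np.zeros((spec.n_clusters, LATENT_DIM))
    centers[: spec.n_clusters, : spec.n_clusters] = (
        spec.separation / np.sqrt(2.0)
    ) * np.eye(spec.n_clusters)
    labels = rng.integers(0, spec.n_clusters, size=spec.n_cells)
    z = centers[labels] + rng.standard_normal((spec.n_cells, LATENT_DIM))
    X = _counts_from_latent(z, spec.n_genes, rng, spec)
    return AnnMatrix(
        X,
        obs_names=[f"cell{i}" for i in range(spec.n_cells)],
        var_names=[f"gene{j}" for j in range(spec.n_genes)],
        obs={"true_cluster": pd.Categorical(labels.astype(str))},
        uns={"fixture_spec": asdict(spec)},
    )


def generate_branching(spec: FixtureSpec | None = None, **kwargs) -> AnnMatrix:
    """Y-shaped trajectory fixture with ``true_time`` and ``true_branch``.

    Cells sit on a piecewise-linear curve through latent program space: the
    trunk runs from the start program to the fork program over time [0, 1/3];
    there the curve forks into two branches that each hand activity over to
    their own terminal program over (1/3, 1].  Consecutive program centers are
    ``separation`` apart and the branches move into orthogonal latent
    dimensions, so the curve never folds back toward its origin.  All
    cell-to-cell variability comes from the count-sampling noise model.
    """
    if spec is None:
        kwargs.setdefault("n_genes", 1000)
        spec = FixtureSpec(kind="branching", **kwargs)
    if spec.n_branches != 2:
        raise ValueError("only n_branches=2 is supported")
    if spec.separation <= 0:
        raise ValueError(f"separation must be positive, got {spec.separation}")
    rng = np.random.default_rng(spec.seed)
    delta = spec.separation
    start = np.zeros(LATENT_DIM)
    fork = delta * np.eye(LATENT_DIM)[1]
    term = {1: fork + delta * np.eye(LATENT_DIM)[2], 2: fork + delta * np.eye(LATENT_DIM)[3]}
    t = rng.uniform(0.0, 1.0, size=spec.n_cells)
    branch = np.where(t <= 1.0 / 3.0, 0, rng.integers(1, 3, size=spec.n_cells))
    z = np.empty((spec.n_cells, LATENT_DIM))
    on_trunk = branch == 0
    s = 3.0 * t[on_trunk, None]
    z[on_trunk] = (1.0 - s) * start + s * fork
    for b in (1, 2):
        m = branch == b
        s = 1.5 * (t[m, None] - 1.0 / 3.0)
        z[m] = (1.0 - s) * fork + s * term[b]
    X = _counts_from_latent(z, spec.n_genes, rng, spec)
    return AnnMatrix(
        X,
        obs_names=[f"cell{i}" for i in range(spec.n_cells)],
        var_names=[f"gene{j}" for j in range(spec.n_genes)],
        obs={
            "true_time": t,
            "true_branch": branch.astype(np.int64),
        },
        uns={"fixture_spec": asdict(spec)},
    )


def generate(kind: str, **kwargs) -> AnnMatrix:
    if kind == "mixture":
        return generate_mixture(FixtureSpec(kind="mixture", **kwargs))
    if kind == "branching":
        kwargs.setdefault("n_genes", 1000)
        return generate_branching(FixtureSpec(kind="branching", **kwargs))
    raise ValueError(f"unknown fixture kind {kind!r}")
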