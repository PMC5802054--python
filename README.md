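# annmat

A scalable toolkit for single-cell gene-expression analysis built around an
annotated data-matrix container. It is aimed at computational biologists who
need the full standard workflow — preprocessing, neighborhood graphs,
clustering, marker genes, trajectory inference, simulation — on matrices that
may not fit comfortably in memory, with every stage testable offline on
synthetic data with known ground truth.

## What it provides

**The container.** `AnnMatrix` couples a cells × genes matrix `X` (dense or
CSR sparse) with per-cell (`obs`) and per-gene (`var`) annotation tables and a
nested metadata map (`uns`). It reads and writes its own HDF5 layout, exports
and re-imports loom files, and imports 10x-style MatrixMarket directories. In
*backed* mode the matrix stays in the HDF5 file and slices are streamed block
by block, so a container can be opened and subset without ever loading `X`.

**The graph engine.** Pairwise Euclidean distances are computed per row block
as `d(q,x)² = ‖q‖² + ‖x‖² − 2·q·x`, so the dominant cost is one matrix
multiplication per block and peak memory stays `O(block · n)`. From the exact
k-nearest-neighbor distances an adaptive Gaussian kernel

    W_ij = exp( −d_ij² / (σ_i² + σ_j²) ),    σ_i = distance to the k-th neighbor

gives symmetric connectivities, and (after optional density normalization
`K̃_ij = W_ij / z_i z_j`, `z_i = Σ_j W_ij`) the row-stochastic random-walk
operator `T`. Every downstream tool reuses this one graph.

**Downstream tools.**

* *Diffusion maps* — eigenpairs of `T` via its symmetric conjugate
  `T_sym = D^{−1/2} K̃ D^{−1/2}`.
* *Diffusion pseudotime (DPT)* — with orthonormal eigenvectors `v_i` of
  `T_sym` and weights `a_i = λ_i/(1−λ_i)`,
  `dpt(x,y)² = Σ_{i≥1} a_i² (v_i(x) − v_i(y))²`; pseudotime is dpt to a chosen
  root cell rescaled to [0, 1]. Branching is detected by ordering cells from
  opposite trajectory tips and splitting where the orderings cease to agree
  (a running Kendall-correlation criterion), with a triangle-degeneracy gate
  so linear trajectories are not split.
* *Louvain clustering* — greedy modularity optimization
  `Q = Σ_c [e_c/m − γ (d_c/2m)²]` with local moving plus graph aggregation.
* *Marker genes* — per-cluster Welch *t* or tie-corrected Wilcoxon rank-sum
  *z* against all other cells, Benjamini–Hochberg adjusted per group.
* *Graph layout* — a seeded Fruchterman–Reingold force-directed embedding.
* *GRN simulator* — boolean gene-regulatory networks relaxed to continuous
  dynamics through a normalized Hill transform
  `h(x) = x^n/(x^n + k^n)·(1+k^n)` and integrated by Euler–Maruyama
  `x ← clamp(x + τ(B(x) − x) + √τ·σ·η)`; snapshot sampling of independent
  trajectories yields synthetic single-cell matrices with attractor structure.
* *Fixtures* — Gaussian-mixture and Y-shaped-trajectory generators with a
  splatter-style log-linear count model (negative-binomial noise, log-normal
  library sizes) and ground-truth labels for every benchmark.

## Worked example

```python
import numpy as np, pandas as pd
import annmat as am

a = am.generate_mixture(n_cells=600, n_genes=300, n_clusters=3,
                        separation=8.0, seed=0)
b = am.recipe_benchmark(a, n_top_genes=100)   # filter → normalize → HVG → log → scale
pc = am.pca(b, n_comps=50, seed=0)
g = am.neighbors(pc.scores, k=15)             # one graph, reused by all tools
res = am.louvain_cluster(g, resolution=1.0, seed=0)
print("louvain: %d communities, modularity Q = %.3f"
      % (res.labels.max() + 1, res.modularity))

b.obs["louvain"] = pd.Categorical(res.labels.astype(str))
rk = am.rank_genes_groups(b, "louvain", method="ttest", n_genes=3)
for grp in rk.groups:
    print(f"cluster {grp}: top markers {list(rk.names[grp])} "
          f"(t = {np.round(rk.scores[grp], 1)})")
```

prints

```
louvain: 3 communities, modularity Q = 0.664
cluster 0: top markers ['gene38', 'gene260', 'gene109'] (t = [48.3 40.8 36.1])
cluster 1: top markers ['gene205', 'gene218', 'gene88'] (t = [48.6 36.9 34.7])
cluster 2: top markers ['gene287', 'gene261', 'gene35'] (t = [40.6 39.9 39.6])
```

The three communities recover the three planted clusters (adjusted Rand index
≥ 0.95 across seeds), and each cluster's top markers are genes whose
log-fold factors load on that cluster's latent program. The same session from
a shell:

```sh
annmat --seed 0 fixture --kind mixture --n-cells 600 --n-genes 300 out.h5
annmat recipe --n-top-genes 100 out.h5
annmat --seed 0 pca out.h5
annmat neighbors --k 15 out.h5
annmat --seed 0 louvain out.h5
annmat rank-genes --groupby louvain out.h5
```

Each stage operates on the container in place (`--output` writes a new file
instead); `diffmap`, `dpt`, `layout`, `simulate`, `import-mtx` and
`export-loom` cover the rest of the pipeline.

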