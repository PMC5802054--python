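# Methods

This note documents the models, conventions and numerical choices behind
`annmat`, and what the synthetic benchmarks do and do not establish.

## The annotated matrix and its on-disk contract

`AnnMatrix` stores `X` (n_obs × n_var, dense ndarray or CSR), two pandas
DataFrames aligned to the axes, and a nested `uns` map. Axis names are
uniquified on construction by appending `-1`, `-2`, … with a warning.
Slicing accepts boolean masks, integer positions, name lists and slices,
returns a lightweight view, and any in-place operation materializes a copy
first (copy-on-write), so pipelines can mutate freely without aliasing bugs.

The HDF5 container stores dense `X` as one 2-D dataset and sparse `X` in
compressed row-major form (`data`/`indices`/`indptr` plus a `shape`
attribute); row-major was chosen because per-cell access dominates
preprocessing. Strings are UTF-8 variable-length; categoricals are integer
codes plus a category list; `uns` mirrors the nested map with an `encoding`
attribute wherever a group is not a plain dict. Backed mode is read-only for
`X`: all reads stream through row blocks of 1024 (`backing.BLOCK_ROWS`), so
peak memory for any slice is `O(block × n_var)` plus the result, and a column
slice of a CSR container is served by streaming row blocks rather than by
loading the matrix. Mutation of a backed matrix requires an explicit
`to_memory()` — a deliberately simple contract that keeps backed/memory
equivalence exactly testable.

Loom export transposes to the loom convention (genes as rows) and flattens
axis tables into `row_attrs`/`col_attrs`; nested `uns` values have no loom
slot and are skipped with a warning. MatrixMarket import relies on
`scipy.io.mmread` and transposes 10x's genes × cells layout.

## Preprocessing conventions

* **Normalization** scales each cell to a target total; the default target is
  the *median* of the pre-normalization totals (scale-free, robust to outlier
  cells). Zero cells are left unchanged with a warning.
* **Dispersion** of a gene is var/mean on normalized, un-logged values
  (sample variance, ddof = 1 everywhere a variance or sd is taken). Genes are
  placed into equal-frequency mean bins (default 20, rank-based so ties split
  deterministically) and the dispersion is standardized within each bin —
  by (mean, sd) for `flavor="meanstd"` or by (median, 1.4826·MAD) for the
  robust default `flavor="medianmad"`; the 1.4826 factor makes the MAD a
  consistent sd estimate so the two flavors are on comparable scales.
  Singleton or zero-spread bins yield z = 0 with a warning rather than
  dropping genes silently. Zero-mean genes have dispersion 0 and are never
  preferred over varying genes.
* **Regression** of covariates is per-gene OLS on `[1, covariates]`, with
  collinear columns dropped (rank-checked greedily) and dense residual output.
* **Scaling** standardizes genes, zeroes zero-variance genes, and clips
  symmetrically when a bound is given (clipping after standardization).
* **PCA** is exact: eigendecomposition of the gene–gene covariance for dense
  input, implicitly centered Lanczos SVD for wide sparse input. Signs are
  fixed by making each loading's largest-magnitude entry positive, so results
  are bit-reproducible.
* The composite recipe is: filter zero-count cells → normalize → HVG
  (medianmad) → subset → normalize → log1p → scale(clip 10), logged step by
  step in `uns["recipe_log"]`.

## Neighbor graph

Distances are exact Euclidean, computed blockwise via the Gram expansion with
negative round-off clamped at zero before the square root. kNN selection is
deterministic: ties break toward the lower index (full stable argsort up to
4096 cells, argpartition plus a stable candidate sort above that), and the
result is provably independent of `block_size`. The kernel width
σ_i = distance to the k-th neighbor adapts to local density; weights are
symmetrized by elementwise max (union of neighborhoods). Density
normalization (`K̃ = Z^{-1} W Z^{-1}`) is on by default, removing the
sampling-density bias of the diffusion geometry. The transition matrix and
its symmetric conjugate are both kept; isolated nodes raise an error that
recommends a larger k. The whole graph serializes into `uns["neighbors"]`
and every downstream tool accepts it unchanged.

## Diffusion maps, pseudotime, branching

Eigenpairs are computed on the symmetric conjugate (ARPACK `eigsh` with a
fixed start vector; dense `eigh` when nearly the full spectrum is needed),
sorted by descending eigenvalue, and back-transformed by `D^{-1/2}`, so the
trivial eigenvector ψ₀ is constant. DPT uses the orthonormal symmetric-basis
eigenvectors: with `a_i = λ_i/(1−λ_i)`,

    dpt(x, y)² = Σ_{i≥1, λ_i<1−ε} a_i² (v_i(x) − v_i(y))²,   ε = 1e-10,

which equals the Euclidean distance between rows of the accumulated operator
`M = (I − (T_sym − v₀v₀ᵀ))⁻¹ − I`; the identity is verified exhaustively in
the tests. Components with λ ≥ 1−ε beyond the trivial one (disconnected
directions) are excluded with a warning. Pseudotime is dpt to the root,
normalized to [0, 1]; raw distances are kept.

Branching uses three tips: the root, μ = argmax dpt(root,·), and
ν = argmax [dpt(root,·) + dpt(μ,·)] — the summed criterion places the third
tip on the other branch rather than back near the root, which a plain
argmax-from-μ often does on Y geometries where both choices are nearly
equidistant. Each tip claims the stretch of cells, ordered by distance from
that tip, over which the orderings from the other two tips remain positively
correlated (the split index maximizes Kendall τ of the head minus Kendall τ
of the tail; minimum segment 5 cells; ties resolve to the earliest index,
i.e. closest to the root). Cells claimed by exactly one tip follow it; cells
claimed by none or several — concentrated near the fork — go to the nearest
tip in dpt, whose decision boundary for a symmetric Y lies exactly at the
fork. A degeneracy gate precedes any split: if
`dpt(root,ν) + dpt(μ,ν) < 1.25 · dpt(root,μ)` the candidate tip lies on the
root–μ path (a linear segment) and no split is made. The trunk keeps label 0;
further splits recurse on the largest segment.

The Fruchterman–Reingold layout uses area = n (so the optimal edge length is
1), attraction `d²/k · W_ij` on each undirected edge once, repulsion `k²/d`
between all pairs (grid-bucketed with a 3k cutoff above 2000 nodes), movement
capped by a linearly cooling temperature from 0.1·√area, and seeded initial
positions.

## Louvain and marker statistics

Modularity follows `Q = Σ_c [e_c/m_w − γ(d_c/2m_w)²]` on the symmetric
weighted graph. The optimizer is the classic two-phase scheme: seeded
random-order local moves (a move requires strictly positive gain; equal-gain
ties prefer the smaller community id for determinism) alternating with
community aggregation until no improvement; one outer-level run, no
multi-restart consensus. Labels are relabeled by decreasing community size.
An exhaustive partition-search reference (`brute_force_best_partition`,
n ≤ 10) backs the tests; on planted two-block random weighted graphs the
implementation attains the exhaustive optimum. On dense structureless random
weighted graphs *any* single-run Louvain — including the reference
implementations it is checked against — can stop at local optima well below
the exhaustive maximum; that regime says more about the modularity landscape
than about an implementation and is not part of the quality gate.

Marker ranking compares each group against all other cells: Welch's t with
Welch–Satterthwaite degrees of freedom, or the rank-sum z with tie correction
under the normal approximation and *no* continuity correction (the convention
of the large-sample tests this mirrors; with n₁ = n₂ = 3 and complete
separation it gives z = −1.964). P-values are two-sided;
Benjamini–Hochberg adjustment is applied across genes within each group.
Log2 fold changes are computed on expm1-backtransformed group means with a
1e-9 pseudocount, clipped at zero so scaled input cannot produce negative
means.

## Boolean-network cell simulator

Rules are boolean expressions (AND/OR/NOT, parentheses) over declared genes,
parsed by recursive descent at model construction, so unknown genes fail
early. The continuous homologue replaces a literal by the normalized Hill
function `h(x) = x^n/(x^n+k^n)·(1+k^n)` — normalized so h(1) = 1, which keeps
attractors near the corners of the unit hypercube — NOT by 1−h, AND by the
product, OR by the probabilistic sum (smooth, unlike max). This normalized
HillCube form is a convention of this package; other boolean-to-continuous
transforms exist. Defaults n = 2, k = 0.5, τ = 0.01, σ = 0.01. Dynamics are
Euler–Maruyama with clamping to [0,1]^G; with σ = 0 halving τ changes the
toggle-switch endpoint by < 1e-3. Snapshot sampling runs one independent
seeded trajectory per cell and records the state at a uniformly drawn step,
mimicking the asynchronous population snapshot of a dissociation experiment.

## Synthetic data: what it emulates and what it does not

Both generators draw a 10-dimensional latent "program activity" per cell and
map it to counts with a splatter-style log-linear model: per-gene log-normal
baselines (sd 1), sparse signed log-fold factors (each latent dimension
regulates ~30% of genes at sd 0.15 per activity unit), per-cell log-normal
size factors (sd 0.3), and gamma–Poisson (negative binomial) sampling at
dispersion 0.1. A signed log-linear map keeps cell identity compositional —
programs regulate genes up and down without inflating totals — which matters
because an additive nonnegative map confounds progression with library size,
a signal that total-count normalization is designed to remove.

The mixture fixture places cluster centers on a scaled simplex (pairwise
distance δ, default 8, in units of the unit within-cluster latent sd). The
branching fixture places cells *on* a piecewise-linear Y-curve through four
program centers (start → fork → two termini, consecutive centers δ apart,
branches turning into orthogonal latent dimensions so the curve never folds
back); all cell-level variability comes from the count noise. Default sizes:
600 × 300 for the mixture and 300 cells × 1000 genes for the trajectory —
the gene count at the scale of a typical HVG selection, which sets the
gene-averaging that trajectory resolution depends on.

Passing the recovery benchmarks (ARI ≥ 0.95 for clustering; Spearman ≥ 0.9
and ≥ 90% branch agreement for DPT) shows the pipeline is correct and
well-conditioned under a faithful noise model with strong, known structure.
It does not establish performance on real tissues, where cluster separations
are weaker and confounders (cell cycle, batch, ambient RNA, doublets) are not
simulated; batch correction and imputation are out of scope.

## Problem sizes and numerical details

Unit tests run on 10–600 cells; the desk-scale check runs the full pipeline
(fixture → recipe → PCA → neighbors → Louvain) on 100,000 × 1,000 sparse
counts in a few minutes and ~3 GB on one CPU, generated and processed in row
blocks throughout. Distance blocks default to 1024 rows. Eigen-solves use a
deterministic start vector; all stochastic stages take explicit seeds, and
the CLI threads one `--seed` through every stage. Degenerate inputs are
handled explicitly rather than silently: zero-count cells (warn, skip),
duplicate points saturating a neighbor list (σ fallback with warning),
isolated graph nodes (error with advice), λ ≈ 1 diffusion components
(excluded with warning), rank-deficient regression designs (drop with
warning), sub-2-cell marker groups (skipped with warning).
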