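"""Preprocessing: filtering, normalization, HVG selection, regression, scaling, PCA.

All operations take and return :class:`~annmat.core.AnnMatrix`; they mutate in
place where noted (views are materialized first) and record provenance flags in
``uns``.  Conventions used throughout: dispersion of a gene is var/mean on
normalized, un-logged values; sample standard deviation uses ddof=1; PCA signs
are fixed so each loading vector's largest-magnitude entry is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import AnnMatrix


@dataclass
class HvgResult:
    """Per-gene mean, dispersion, within-bin standardized dispersion, and mask."""

    means: np.ndarray
    dispersions: np.ndarray
    dispersions_norm: np.ndarray
    highly_variable: np.ndarray


@dataclass
class PcaResult:
    components: np.ndarray  # n_var × n_comps orthonormal loadings
    scores: np.ndarray  # n_obs × n_comps
    explained_variance_ratio: np.ndarray


def _row_sums(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel() if sp.issparse(X) else X.sum(axis=1)


def _col_mean_var(X, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and variance without densifying."""
    n = X.shape[0]
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        mean = X.mean(axis=0)
        sq = np.mean(np.asarray(X) ** 2, axis=0)
    var = np.maximum(sq - mean**2, 0.0)
    if ddof:
        var *= n / max(n - ddof, 1)
    return mean, var


def filter_axis(
    a: AnnMatrix,
    axis: str,
    min_counts: float | None = None,
    min_entities: int | None = None,
):
    """Drop low-signal observations or variables.

    For ``axis='obs'``: keep cells with total count ≥ ``min_counts`` and/or
    detected in ≥ ``min_entities`` genes.  For ``axis='var'``: keep genes with
    total count ≥ ``min_counts`` and/or detected in ≥ ``min_entities`` cells.
    Returns ``(filtered, report)`` where the report lists removed names.
    """
    if axis not in ("obs", "var"):
        raise ValueError(f"axis must be 'obs' or 'var', got {axis!r}")
    if min_counts is None and min_entities is None:
        raise ValueError("provide at least one of min_counts, min_entities")
    X = a.to_memory().X
    ax = 1 if axis == "obs" else 0
    keep = np.ones(a.shape[0 if axis == "obs" else 1], dtype=bool)
    if min_counts is not None:
        totals = np.asarray(X.sum(axis=ax)).ravel()
        keep &= totals >= min_counts
    if min_entities is not None:
        nnz = (
            np.asarray((X != 0).sum(axis=ax)).ravel()
            if sp.issparse(X)
            else (np.asarray(X) != 0).sum(axis=ax)
        )
        keep &= nnz >= min_entities
    if not keep.any():
        raise ValueError(
            f"filter_axis would remove every {axis}; review the thresholds"
        )
    names = a.obs_names if axis == "obs" else a.var_names
    report = {"axis": axis, "removed": list(names[~keep]), "n_removed": int((~keep).sum())}
    out = a[keep, :] if axis == "obs" else a[:, keep]
    out._materialize()
    return out, report


def normalize_total(a: AnnMatrix, target_sum: float | None = None) -> AnnMatrix:
    """Scale each cell so its total count equals ``target_sum``.

    Default target is the median of the pre-normalization row sums (scale-free
    and robust to outlier cells).  Zero rows are left unchanged with a warning.
    """
    a._materialize()
    X = a.X
    if sp.issparse(X):
        if X.data.size and X.data.min() < 0:
            raise ValueError("normalize_total requires nonnegative X")
    elif np.asarray(X).size and np.asarray(X).min() < 0:
        raise ValueError("normalize_total requires nonnegative X")
    sums = _row_sums(X)
    if target_sum is None:
        target_sum = float(np.median(sums))
    if target_sum <= 0:
        raise ValueError(f"target_sum must be positive, got {target_sum}")
    zero = sums == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-count row(s) left unchanged", UserWarning)
    factors = np.ones_like(sums, dtype=np.float64)
    factors[~zero] = target_sum / sums[~zero]
    if sp.issparse(X):
        a.X = sp.diags(factors) @ X.astype(np.float64)
    else:
        a.X = np.asarray(X, dtype=np.float64) * factors[:, None]
    a.uns["normalize_total_target"] = float(target_sum)
    return a


def log1p(a: AnnMatrix) -> AnnMatrix:
    """Elementwise ln(1+x); preserves sparsity; idempotence-guarded via a flag."""
    a._materialize()
    if a.uns.get("log1p"):
        warnings.warn("matrix already log1p-transformed; no-op", UserWarning)
        return a
    X = a.X
    if sp.issparse(X):
        X = X.astype(np.float64)
        np.log1p(X.data, out=X.data)
        a.X = X
    else:
        a.X = np.log1p(np.asarray(X, dtype=np.float64))
    a.uns["log1p"] = True
    return a


def highly_variable_genes(
    a: AnnMatrix,
    n_top: int,
    n_bins: int = 20,
    flavor: str = "medianmad",
) -> HvgResult:
    """Select the ``n_top`` genes with highest within-bin standardized dispersion.

    Genes are binned into ``n_bins`` equal-frequency bins of their mean; within
    each bin the dispersion d = var/mean is standardized by (mean, std) for
    ``flavor='meanstd'`` or (median, scaled MAD) for ``flavor='medianmad'``.
    Bins with a single gene or zero spread yield z = 0 with a warning.  Genes
    with zero mean have dispersion 0 and are never preferred over varying genes.
    """
    if flavor not in ("meanstd", "medianmad"):
        raise ValueError(f"flavor must be 'meanstd' or 'medianmad', got {flavor!r}")
    n_var = a.n_var
    if n_top > n_var:
        raise ValueError(f"n_top={n_top} exceeds n_var={n_var}")
    X = a.to_memory().X
    mean, var = _col_mean_var(X, ddof=1)
    disp = np.zeros(n_var)
    nz = mean > 0
    disp[nz] = var[nz] / mean[nz]

    # equal-frequency bins on the mean (rank-based so ties split deterministically)
    ranks = pd.Series(mean).rank(method="first").to_numpy()
    n_bins_eff = min(n_bins, n_var)
    bins = np.minimum((ranks - 1) * n_bins_eff // n_var, n_bins_eff - 1).astype(int)

    z = np.zeros(n_var)
    degenerate = 0
    for b in np.unique(bins):
        in_bin = bins == b
        d = disp[in_bin]
        if flavor == "meanstd":
            center = d.mean()
            scale = d.std(ddof=1) if in_bin.sum() > 1 else 0.0
        else:
            center = np.median(d)
            scale = 1.4826 * np.median(np.abs(d - center))
        if in_bin.sum() < 2 or scale == 0:
            degenerate += 1
            z[in_bin] = 0.0
        else:
            z[in_bin] = (d - center) / scale
    if degenerate:
        warnings.warn(
            f"{degenerate} dispersion bin(s) degenerate (singleton or zero spread); "
            "their genes get z=0",
            UserWarning,
        )

    # rank by z; zero-mean genes go last so they are picked only when n_top forces it
    key = np.where(nz, z, -np.inf)
    order = np.lexsort((np.arange(n_var), -key))  # stable: ties keep gene order
    mask = np.zeros(n_var, dtype=bool)
    mask[order[:n_top]] = True
    return HvgResult(mean, disp, z, mask)


def regress_out(a: AnnMatrix, covariate_cols: list[str]) -> AnnMatrix:
    """Replace X by residuals of per-gene OLS on [intercept, covariates].

    Densifies X (residuals are dense).  Collinear covariates are dropped with a
    warning.
    """
    a._materialize()
    missing = [c for c in covariate_cols if c not in a.obs.columns]
    if missing:
        raise KeyError(f"obs columns not found: {missing}")
    cov = a.obs[list(covariate_cols)].to_numpy(dtype=np.float64)
    n = a.n_obs
    design = np.column_stack([np.ones(n), cov])
    # greedy drop of columns that do not increase rank (intercept always kept)
    keep = [0]
    for j in range(1, design.shape[1]):
        if np.linalg.matrix_rank(design[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            warnings.warn(
                f"covariate {covariate_cols[j - 1]!r} is collinear with the rest; dropped",
                UserWarning,
            )
    D = design[:, keep]
    X = a.X.toarray() if sp.issparse(a.X) else np.asarray(a.X, dtype=np.float64)
    coef, *_ = np.linalg.lstsq(D, X, rcond=None)
    a.X = X - D @ coef
    return a


def scale_clip(a: AnnMatrix, max_value: float | None = None) -> AnnMatrix:
    """Standardize each gene (mean 0, sample std 1); optionally clip symmetrically.

    Zero-variance genes are set to 0.  Densifies (centering destroys sparsity).
    """
    a._materialize()
    X = a.X.toarray() if sp.issparse(a.X) else np.asarray(a.X, dtype=np.float64)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    out = X - mean
    nz = std > 0
    out[:, nz] /= std[nz]
    out[:, ~nz] = 0.0
    if max_value is not None:
        if max_value <= 0:
            raise ValueError("max_value must be positive")
        np.clip(out, -max_value, max_value, out=out)
    a.X = out
    return a


def pca(a: AnnMatrix, n_comps: int, seed: int = 0) -> PcaResult:
    """Principal components of the centered matrix.

    Dense inputs use an exact eigendecomposition of the gene–gene covariance;
    sparse inputs use an implicitly centered Lanczos SVD (seeded start vector).
    Each loading vector's largest-magnitude entry is made positive so results
    are reproducible.
    """
    n_obs, n_var = a.shape
    if not 1 <= n_comps <= min(n_obs, n_var):
        raise ValueError(f"n_comps must be in [1, {min(n_obs, n_var)}], got {n_comps}")
    X = a.to_memory().X

    if sp.issparse(X) and n_var > 2000:
        from scipy.sparse.linalg import LinearOperator, svds

        mean = np.asarray(X.mean(axis=0)).ravel()
        ones = np.ones(n_obs)

        def mv(v):
            return X @ v - ones * (mean @ v)

        def rmv(v):
            return X.T @ v - mean * (ones @ v)

        op = LinearOperator((n_obs, n_var), matvec=mv, rmatvec=rmv)
        rng = np.random.default_rng(seed)
        u, s, vt = svds(op, k=n_comps, v0=rng.standard_normal(min(n_obs, n_var)))
        order = np.argsort(-s)
        s, vt = s[order], vt[order]
        comps = vt.T
        expl = s**2 / (n_obs - 1)
        total = _col_mean_var(X, ddof=1)[1].sum()
    else:
        Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=np.float64)
        Xc = Xd - Xd.mean(axis=0)
        cov = (Xc.T @ Xc) / (n_obs - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(-evals)[:n_comps]
        comps = evecs[:, order]
        expl = np.maximum(evals[order], 0.0)
        total = np.maximum(evals, 0.0).sum()

    # deterministic sign: largest-|.| entry of each loading vector positive
    flip = comps[np.argmax(np.abs(comps), axis=0), np.arange(n_comps)] < 0
    comps[:, flip] *= -1.0
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        scores = X @ comps - mean @ comps
    else:
        scores = (np.asarray(X) - np.asarray(X).mean(axis=0)) @ comps
    ratio = expl / total if total > 0 else np.zeros_like(expl)
    return PcaResult(components=comps, scores=np.asarray(scores), explained_variance_ratio=ratio)


def recipe_benchmark(a: AnnMatrix, n_top_genes: int = 1000) -> AnnMatrix:
    """Composite preprocessing: filter → normalize → HVG → subset → normalize →
    log1p → scale(clip 10), logging each step in ``uns['recipe_log']``."""
    log: list[str] = []
    a, rep = filter_axis(a, "obs", min_counts=1)
    log.append(f"filter_obs(min_counts=1): removed {rep['n_removed']}")
    a = normalize_total(a)
    log.append("normalize_total(median)")
    hvg = highly_variable_genes(a, n_top=min(n_top_genes, a.n_var), flavor="medianmad")
    log.append(f"highly_variable_genes(n_top={int(hvg.highly_variable.sum())}, medianmad)")
    a = a[:, hvg.highly_variable]
    a._materialize()
    log.append("subset_to_hvg")
    a = normalize_total(a)
    log.append("normalize_total(median)")
    a = log1p(a)
    log.append("log1p")
    a = scale_clip(a, max_value=10)
    log.append("scale_clip(10)")
    a.uns["recipe_log"] = log
    return a
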