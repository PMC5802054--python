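"""Annotated observations × variables matrix.

The :class:`AnnMatrix` container couples a numeric data matrix ``X`` (cells ×
genes in the single-cell setting, dense or sparse) with per-observation and
per-variable annotation tables (pandas DataFrames) and a nested mapping of
unstructured metadata ``uns``.  The container can live fully in memory or stay
*backed* by an HDF5 file, in which case ``X`` is read lazily block by block
and is never resident in memory as a whole.

Slicing with ``a[obs_selector, var_selector]`` accepts boolean masks, integer
positions, name lists and slices on either axis and subsets ``X``, ``obs`` and
``var`` consistently; it behaves identically in backed and memory mode.
"""

from __future__ import annotations

import warnings
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ShapeError(ValueError):
    """Matrix / annotation dimension mismatch."""


def make_names_unique(names: Sequence[str], axis: str = "axis") -> list[str]:
    """Uniquify duplicate names by appending ``-1``, ``-2``, ... with a warning."""
    names = [str(n) for n in names]
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for name in names:
        if name in seen:
            n_dup += 1
            seen[name] += 1
            new = f"{name}-{seen[name]}"
            while new in seen:
                seen[name] += 1
                new = f"{name}-{seen[name]}"
            seen[new] = 0
            out.append(new)
        else:
            seen[name] = 0
            out.append(name)
    if n_dup:
        warnings.warn(
            f"{n_dup} duplicate {axis} name(s) uniquified by appending '-<i>'",
            UserWarning,
            stacklevel=3,
        )
    return out


def _default_names(n: int, prefix: str) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def _normalize_selector(sel, index: pd.Index, axis: str) -> np.ndarray:
    """Turn any supported selector into an integer position array."""
    n = len(index)
    if sel is None:
        return np.arange(n)
    if isinstance(sel, slice):
        return np.arange(n)[sel]
    sel = np.asarray(sel)
    if sel.dtype == bool:
        if sel.shape[0] != n:
            raise ShapeError(
                f"boolean {axis} selector has length {sel.shape[0]}, expected {n}"
            )
        return np.flatnonzero(sel)
    if sel.dtype.kind in "iu":
        return sel.astype(np.intp)
    # name list
    sel = sel.astype(object)
    indexer = index.get_indexer(sel)
    if (indexer < 0).any():
        missing = list(sel[indexer < 0])
        raise KeyError(f"{axis} names not found: {missing}")
    return indexer.astype(np.intp)


class AnnMatrix:
    """Annotated data matrix of shape ``n_obs × n_var``.

    Parameters
    ----------
    X
        Dense array or scipy sparse matrix; rows are observations.
    obs_names, var_names
        Axis names; uniquified with a warning if duplicated.
    obs, var
        Optional column mappings (or DataFrames) aligned to the axes.
    uns
        Unstructured metadata: a string-keyed, arbitrarily nested mapping of
        scalars, arrays, string lists, sparse matrices, and sub-mappings.
    copy
        Copy ``X`` on construction (default: keep the caller's matrix).
    """

    def __init__(
        self,
        X,
        obs_names: Sequence[str] | None = None,
        var_names: Sequence[str] | None = None,
        obs: Mapping[str, Any] | pd.DataFrame | None = None,
        var: Mapping[str, Any] | pd.DataFrame | None = None,
        uns: dict | None = None,
        *,
        copy: bool = False,
    ):
        from .backing import BackedMatrix

        if isinstance(X, BackedMatrix):
            pass
        elif sp.issparse(X):
            X = X.tocsr(copy=copy)
        else:
            X = np.array(X, copy=copy) if copy else np.asarray(X)
            if X.ndim != 2:
                raise ShapeError(f"X must be 2-D, got {X.ndim}-D")
        n_obs, n_var = X.shape

        if obs_names is None:
            obs_names = (
                obs.index if isinstance(obs, pd.DataFrame) and obs.index.dtype == object
                else _default_names(n_obs, "obs")
            )
        if var_names is None:
            var_names = (
                var.index if isinstance(var, pd.DataFrame) and var.index.dtype == object
                else _default_names(n_var, "var")
            )
        if len(obs_names) != n_obs:
            raise ShapeError(
                f"obs axis: X has {n_obs} rows but {len(obs_names)} obs_names given"
            )
        if len(var_names) != n_var:
            raise ShapeError(
                f"var axis: X has {n_var} columns but {len(var_names)} var_names given"
            )
        obs_names = make_names_unique(obs_names, "obs")
        var_names = make_names_unique(var_names, "var")

        self._X = X
        self.obs = self._build_axis_df(obs, obs_names, n_obs, "obs")
        self.var = self._build_axis_df(var, var_names, n_var, "var")
        self.uns: dict = dict(uns) if uns else {}
        self._is_view = False

    @staticmethod
    def _build_axis_df(cols, names, n, axis) -> pd.DataFrame:
        df = pd.DataFrame(index=pd.Index(names, name=None))
        if cols is None:
            return df
        if isinstance(cols, pd.DataFrame):
            cols = {k: cols[k].to_numpy() for k in cols.columns}
        for key, values in cols.items():
            values = np.asarray(values) if not isinstance(values, pd.Categorical) else values
            if len(values) != n:
                raise ShapeError(
                    f"{axis} column {key!r} has length {len(values)}, expected {n}"
                )
            df[key] = values
        return df

    # -- basic properties ---------------------------------------------------

    @property
    def X(self):
        return self._X

    @X.setter
    def X(self, value):
        if value.shape != self.shape:
            raise ShapeError(f"new X shape {value.shape} != {self.shape}")
        self._X = value.tocsr() if sp.issparse(value) else np.asarray(value)

    @property
    def n_obs(self) -> int:
        return self._X.shape[0]

    @property
    def n_var(self) -> int:
        return self._X.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._X.shape

    @property
    def obs_names(self) -> pd.Index:
        return self.obs.index

    @property
    def var_names(self) -> pd.Index:
        return self.var.index

    @property
    def isbacked(self) -> bool:
        from .backing import BackedMatrix

        return isinstance(self._X, BackedMatrix)

    @property
    def issparse(self) -> bool:
        from .backing import BackedMatrix

        if isinstance(self._X, BackedMatrix):
            return self._X.is_sparse
        return sp.issparse(self._X)

    def __repr__(self) -> str:
        kind = "backed" if self.isbacked else ("sparse" if self.issparse else "dense")
        s = f"AnnMatrix {self.n_obs} obs × {self.n_var} var ({kind})"
        if len(self.obs.columns):
            s += f"\n    obs: {list(self.obs.columns)}"
        if len(self.var.columns):
            s += f"\n    var: {list(self.var.columns)}"
        if self.uns:
            s += f"\n    uns: {list(self.uns)}"
        return s

    # -- slicing ------------------------------------------------------------

    def __getitem__(self, key) -> "AnnMatrix":
        if not isinstance(key, tuple):
            key = (key, slice(None))
        if len(key) != 2:
            raise IndexError("AnnMatrix supports [obs_selector, var_selector]")
        obs_sel, var_sel = key
        oi = _normalize_selector(obs_sel, self.obs_names, "obs")
        vi = _normalize_selector(var_sel, self.var_names, "var")

        if self.isbacked:
            Xs = self._X.read_submatrix(oi, vi)
        else:
            Xs = self._X[oi][:, vi] if sp.issparse(self._X) else self._X[np.ix_(oi, vi)]
        out = AnnMatrix.__new__(AnnMatrix)
        out._X = Xs
        out.obs = self.obs.iloc[oi]
        out.var = self.var.iloc[vi]
        out.uns = self.uns
        out._is_view = True
        return out

    def _materialize(self) -> None:
        """Detach a view before in-place mutation (copy-on-write contract)."""
        if self._is_view:
            self._X = self._X.copy()
            self.obs = self.obs.copy()
            self.var = self.var.copy()
            self.uns = dict(self.uns)
            self._is_view = False

    def copy(self) -> "AnnMatrix":
        import copy as _copy

        X = self.to_memory()._X.copy() if self.isbacked else self._X.copy()
        out = AnnMatrix.__new__(AnnMatrix)
        out._X = X
        out.obs = self.obs.copy()
        out.var = self.var.copy()
        out.uns = _copy.deepcopy(self.uns)
        out._is_view = False
        return out

    def to_memory(self) -> "AnnMatrix":
        """Return an in-memory equivalent (no-op if already in memory)."""
        if not self.isbacked:
            return self
        out = AnnMatrix.__new__(AnnMatrix)
        out._X = self._X.to_memory()
        out.obs = self.obs.copy()
        out.var = self.var.copy()
        out.uns = dict(self.uns)
        out._is_view = False
        return out


def new_annmatrix(
    X,
    obs_names=None,
    var_names=None,
    obs=None,
    var=None,
    uns=None,
) -> AnnMatrix:
    """Construct an in-memory :class:`AnnMatrix` (functional alias)."""
    return AnnMatrix(X, obs_names, var_names, obs=obs, var=var, uns=uns)


def slice_annmatrix(a: AnnMatrix, obs_selector=None, var_selector=None) -> AnnMatrix:
    """Subset on both axes; see :meth:`AnnMatrix.__getitem__`."""
    return a[obs_selector, var_selector]
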