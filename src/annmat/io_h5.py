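"""Container I/O: own HDF5 layout, loom export/import, 10x MatrixMarket import.

HDF5 container layout
---------------------
``/`` attrs ``n_obs``, ``n_var``; ``X`` as one 2-D dataset (dense) or a group
with ``data``/``indices``/``indptr`` datasets plus a ``shape`` attribute
(compressed row-major sparse); groups ``obs`` and ``var`` each holding an
``_index`` dataset plus one dataset per annotation column (categorical columns
as a subgroup ``{codes, categories}``); group ``uns`` mirroring the nested
metadata map.  Strings are UTF-8 variable length.  A write→read round trip in
memory mode is the identity on ``X``, ``obs``, ``var`` and ``uns``.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.io

import h5py

from .backing import BackedMatrix, FileBacking
from .core import AnnMatrix, make_names_unique

_STR = h5py.string_dtype(encoding="utf-8")


class FormatError(ValueError):
    """Container file does not follow the expected layout."""


# -- writers -----------------------------------------------------------------


def _write_sparse(parent: h5py.Group, key: str, m: sp.spmatrix) -> None:
    m = sp.csr_matrix(m)
    g = parent.create_group(key)
    g.attrs["encoding"] = "csr"
    g.attrs["shape"] = np.asarray(m.shape, dtype=np.int64)
    g.create_dataset("data", data=m.data)
    g.create_dataset("indices", data=m.indices)
    g.create_dataset("indptr", data=m.indptr)


def _write_string_array(parent: h5py.Group, key: str, values) -> None:
    ds = parent.create_dataset(key, data=np.asarray(values, dtype=object), dtype=_STR)
    ds.attrs["encoding"] = "string-array"


def _write_column(parent: h5py.Group, key: str, values) -> None:
    if isinstance(values, pd.Series):
        values = values.array if isinstance(values.dtype, pd.CategoricalDtype) else values.to_numpy()
    if isinstance(values, pd.Categorical):
        g = parent.create_group(key)
        g.attrs["encoding"] = "categorical"
        g.create_dataset("codes", data=np.asarray(values.codes, dtype=np.int32))
        _write_string_array(g, "categories", [str(c) for c in values.categories])
        return
    values = np.asarray(values)
    if values.dtype.kind in "OU":
        _write_string_array(parent, key, values.astype(str))
    else:
        parent.create_dataset(key, data=values)


def _write_axis(parent: h5py.Group, key: str, df: pd.DataFrame) -> None:
    g = parent.create_group(key)
    _write_string_array(g, "_index", [str(n) for n in df.index])
    for col in df.columns:
        _write_column(g, str(col), df[col])


def _write_uns_value(parent: h5py.Group, key: str, value) -> None:
    key = str(key)
    if isinstance(value, dict):
        g = parent.create_group(key)
        g.attrs["encoding"] = "dict"
        for k, v in value.items():
            _write_uns_value(g, k, v)
    elif sp.issparse(value):
        _write_sparse(parent, key, value)
    elif isinstance(value, str):
        ds = parent.create_dataset(key, data=value, dtype=_STR)
        ds.attrs["encoding"] = "string"
    elif isinstance(value, (bool, np.bool_)):
        parent.create_dataset(key, data=np.bool_(value))
    elif isinstance(value, (int, float, np.integer, np.floating)):
        parent.create_dataset(key, data=value)
    elif isinstance(value, pd.Categorical):
        _write_column(parent, key, value)
    else:
        arr = np.asarray(value)
        if arr.dtype.kind in "OU":
            _write_string_array(parent, key, arr.astype(str))
        else:
            parent.create_dataset(key, data=arr)


def write_container(a: AnnMatrix, path) -> None:
    """Write an :class:`AnnMatrix` to the HDF5 container at ``path``."""
    a = a.to_memory()
    with h5py.File(path, "w") as f:
        f.attrs["n_obs"] = a.n_obs
        f.attrs["n_var"] = a.n_var
        X = a.X
        if sp.issparse(X):
            _write_sparse(f, "X", X)
        else:
            ds = f.create_dataset("X", data=np.asarray(X))
            ds.attrs["encoding"] = "array"
        _write_axis(f, "obs", a.obs)
        _write_axis(f, "var", a.var)
        uns = f.create_group("uns")
        uns.attrs["encoding"] = "dict"
        for k, v in a.uns.items():
            _write_uns_value(uns, k, v)


# -- readers -----------------------------------------------------------------


def _decode_strings(arr: np.ndarray) -> np.ndarray:
    return np.asarray(
        [v.decode("utf-8") if isinstance(v, bytes) else str(v) for v in arr.ravel()],
        dtype=object,
    ).reshape(arr.shape)


def _read_sparse(g: h5py.Group) -> sp.csr_matrix:
    shape = tuple(int(s) for s in g.attrs["shape"])
    return sp.csr_matrix((g["data"][:], g["indices"][:], g["indptr"][:]), shape=shape)


def _read_value(node):
    if isinstance(node, h5py.Group):
        enc = node.attrs.get("encoding", "dict")
        if enc == "csr":
            return _read_sparse(node)
        if enc == "categorical":
            codes = node["codes"][:]
            cats = _decode_strings(node["categories"][:])
            return pd.Categorical.from_codes(codes, categories=list(cats))
        if enc == "dict":
            return {k: _read_value(node[k]) for k in node}
        raise FormatError(f"unknown encoding tag {enc!r} at {node.name}")
    data = node[()]
    enc = node.attrs.get("encoding")
    if enc == "string":
        return data.decode("utf-8") if isinstance(data, bytes) else str(data)
    if enc == "string-array" or (isinstance(data, np.ndarray) and data.dtype.kind in "OS"):
        return _decode_strings(np.asarray(data))
    if np.isscalar(data) or isinstance(data, np.generic):
        return data.item() if isinstance(data, np.generic) else data
    return np.asarray(data)


def _read_axis(f: h5py.File, key: str) -> pd.DataFrame:
    if key not in f:
        raise FormatError(f"missing required group {key!r}")
    g = f[key]
    if "_index" not in g:
        raise FormatError(f"missing required dataset {key}/_index")
    index = pd.Index(_decode_strings(g["_index"][:]))
    df = pd.DataFrame(index=index)
    for col in g:
        if col == "_index":
            continue
        df[col] = _read_value(g[col])
    return df


def read_container(path, backed: bool = False) -> AnnMatrix:
    """Read a container; ``backed=True`` keeps ``X`` on disk (read-only)."""
    path = str(path)
    with h5py.File(path, "r") as f:
        if "X" not in f:
            raise FormatError("missing required dataset or group 'X'")
        node = f["X"]
        is_sparse = isinstance(node, h5py.Group)
        if is_sparse:
            if node.attrs.get("encoding") != "csr":
                raise FormatError(
                    f"unknown encoding tag {node.attrs.get('encoding')!r} for X"
                )
            shape = tuple(int(s) for s in node.attrs["shape"])
            dtype = node["data"].dtype
        else:
            shape = node.shape
            dtype = node.dtype
        obs = _read_axis(f, "obs")
        var = _read_axis(f, "var")
        uns = _read_value(f["uns"]) if "uns" in f else {}
        X_mem = None if backed else (_read_sparse(node) if is_sparse else node[:])

    out = AnnMatrix.__new__(AnnMatrix)
    if backed:
        out._X = BackedMatrix(FileBacking(path, "r"), is_sparse, shape, dtype)
    else:
        out._X = X_mem
    out.obs = obs
    out.var = var
    out.uns = uns
    out._is_view = False
    return out


# -- loom --------------------------------------------------------------------


def export_loom(a: AnnMatrix, path) -> None:
    """Write a loom file: ``matrix`` is variables × observations.

    Variable annotations go to ``row_attrs`` (incl. ``var_names``), observation
    annotations to ``col_attrs`` (incl. ``obs_names``).  Nested ``uns`` values
    have no loom slot and are skipped with a warning.
    """
    a = a.to_memory()
    with h5py.File(path, "w") as f:
        X = a.X
        M = X.T.toarray() if sp.issparse(X) else np.asarray(X).T
        f.create_dataset("matrix", data=M)
        row = f.create_group("row_attrs")
        _write_string_array(row, "var_names", [str(n) for n in a.var_names])
        for col in a.var.columns:
            _write_column(row, str(col), a.var[col])
        colg = f.create_group("col_attrs")
        _write_string_array(colg, "obs_names", [str(n) for n in a.obs_names])
        for col in a.obs.columns:
            _write_column(colg, str(col), a.obs[col])
        if a.uns:
            warnings.warn(
                f"loom has no slot for unstructured metadata; skipped keys {list(a.uns)}",
                UserWarning,
            )


def import_loom(path) -> AnnMatrix:
    """Read a loom file written by :func:`export_loom` (transposing back)."""
    with h5py.File(path, "r") as f:
        if "matrix" not in f:
            raise FormatError("missing required dataset 'matrix'")
        X = f["matrix"][:].T
        var = {k: _read_value(f["row_attrs"][k]) for k in f.get("row_attrs", {})}
        obs = {k: _read_value(f["col_attrs"][k]) for k in f.get("col_attrs", {})}
    var_names = var.pop("var_names", None)
    obs_names = obs.pop("obs_names", None)
    return AnnMatrix(X, obs_names=obs_names, var_names=var_names, obs=obs, var=var)


# -- 10x MatrixMarket ----------------------------------------------------------


def import_mtx_10x(dir_path) -> AnnMatrix:
    """Import a 10x-style directory (matrix.mtx + genes.tsv + barcodes.tsv).

    The MatrixMarket file stores genes as rows and cells as columns; the result
    is transposed to cells × genes with sparse ``X``, ``var_names`` from the
    gene-symbol column and a ``gene_id`` var column from the gene-id column.
    """
    d = Path(dir_path)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing sidecar file {name} in {d}")
    try:
        M = scipy.io.mmread(d / "matrix.mtx")
    except Exception as e:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"malformed matrix.mtx: {e}") from e
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None, dtype=str)
    if len(genes) != M.shape[0]:
        raise FormatError(
            f"genes.tsv has {len(genes)} rows but matrix.mtx declares {M.shape[0]} genes"
        )
    if len(barcodes) != M.shape[1]:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx declares "
            f"{M.shape[1]} cells"
        )
    gene_ids = genes.iloc[:, 0].tolist()
    symbols = genes.iloc[:, 1].tolist() if genes.shape[1] > 1 else gene_ids
    X = sp.csr_matrix(M.T)
    return AnnMatrix(
        X,
        obs_names=barcodes.iloc[:, 0].tolist(),
        var_names=make_names_unique(symbols, "var"),
        var={"gene_id": gene_ids},
    )
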