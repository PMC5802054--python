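"""On-disk backing for the data matrix.

A :class:`BackedMatrix` stands in for ``X`` when a container is opened in
backed mode: the matrix stays in the HDF5 file and reads go through row-block
streaming, so no operation materializes the full matrix.  Backed ``X`` is
read-only; mutation requires :meth:`AnnMatrix.to_memory` first.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

import h5py

#: rows fetched per streaming block when subsetting a backed matrix
BLOCK_ROWS = 1024


class FileBacking:
    """Handle on the container file a backed matrix reads from."""

    def __init__(self, path: str, mode: str = "r"):
        if mode not in ("r", "r+"):
            raise ValueError("mode must be 'r' (read) or 'r+' (read-write)")
        self.path = str(path)
        self.mode = mode
        self._file: h5py.File | None = h5py.File(path, mode)

    @property
    def open(self) -> bool:
        return self._file is not None and bool(self._file.id.valid)

    @property
    def file(self) -> h5py.File:
        if not self.open:
            self._file = h5py.File(self.path, self.mode)
        return self._file

    def close(self) -> None:
        if self._file is not None and self._file.id.valid:
            self._file.close()

    def __repr__(self) -> str:
        state = "open" if self.open else "closed"
        return f"FileBacking({self.path!r}, mode={self.mode!r}, {state})"


class BackedMatrix:
    """Lazy view of the on-disk ``X`` (dense dataset or CSR group)."""

    def __init__(self, backing: FileBacking, is_sparse: bool, shape, dtype):
        self.backing = backing
        self.is_sparse = bool(is_sparse)
        self.shape = tuple(int(s) for s in shape)
        self.dtype = np.dtype(dtype)

    # -- low-level block reads ------------------------------------------------

    def _node(self):
        return self.backing.file["X"]

    def read_rows(self, start: int, stop: int):
        """Contiguous row block ``[start, stop)``; dense array or CSR matrix."""
        node = self._node()
        if not self.is_sparse:
            return node[start:stop]
        indptr = node["indptr"][start : stop + 1]
        lo, hi = int(indptr[0]), int(indptr[-1])
        data = node["data"][lo:hi]
        indices = node["indices"][lo:hi]
        return sp.csr_matrix(
            (data, indices, indptr - lo), shape=(stop - start, self.shape[1])
        )

    def read_submatrix(self, rows: np.ndarray, cols: np.ndarray):
        """Fetch an arbitrary row/column subset by streaming row blocks.

        Peak memory is O(BLOCK_ROWS × n_var + result); the full matrix is
        never loaded.
        """
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        n_obs = self.shape[0]
        if rows.size and (rows.min() < 0 or rows.max() >= n_obs):
            raise IndexError("row selector out of range")
        if cols.size and (cols.min() < 0 or cols.max() >= self.shape[1]):
            raise IndexError("column selector out of range")
        order = np.argsort(rows, kind="stable")
        sorted_rows = rows[order]
        pieces = []
        i = 0
        while i < sorted_rows.size:
            start = int(sorted_rows[i])
            stop = min(start + BLOCK_ROWS, n_obs)
            j = int(np.searchsorted(sorted_rows, stop, side="left"))
            block = self.read_rows(start, stop)
            local = sorted_rows[i:j] - start
            piece = block[local][:, cols]
            pieces.append(piece)
            i = j
        if not pieces:
            empty = (
                sp.csr_matrix((0, cols.size), dtype=self.dtype)
                if self.is_sparse
                else np.empty((0, cols.size), dtype=self.dtype)
            )
            return empty
        stacked = sp.vstack(pieces, format="csr") if self.is_sparse else np.vstack(pieces)
        # undo the sort so the result follows the caller's row order
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        return stacked[inv]

    def to_memory(self):
        """Materialize the full matrix by streaming blocks."""
        pieces = [
            self.read_rows(s, min(s + BLOCK_ROWS, self.shape[0]))
            for s in range(0, self.shape[0], BLOCK_ROWS)
        ]
        if self.is_sparse:
            return sp.vstack(pieces, format="csr") if pieces else sp.csr_matrix(self.shape)
        return np.vstack(pieces) if pieces else np.empty(self.shape, dtype=self.dtype)

    def __getitem__(self, key):
        """Element / row access through the backing contract."""
        if not isinstance(key, tuple):
            key = (key, slice(None))
        rows, cols = key
        n_obs, n_var = self.shape
        rows = np.arange(n_obs)[rows] if isinstance(rows, slice) else np.atleast_1d(rows)
        cols = np.arange(n_var)[cols] if isinstance(cols, slice) else np.atleast_1d(cols)
        sub = self.read_submatrix(rows.astype(np.intp), cols.astype(np.intp))
        if sub.shape == (1, 1):
            return sub[0, 0] if not sp.issparse(sub) else sub.toarray()[0, 0]
        return sub

    def __repr__(self) -> str:
        kind = "csr" if self.is_sparse else "dense"
        return f"BackedMatrix({self.shape[0]}×{self.shape[1]} {kind}, {self.backing!r})"
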