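"""Expression containers with a uniform block-access contract.

The whole package touches expression data only through
:meth:`ExpressionStore.fetch_block`, which returns a dense ``|cells| x |genes|``
float64 array for arbitrary index subsets.  This is what lets the driver keep
its working set at ``O(N * |J| + |I| * M)`` entries: the full matrix is never
densified, whatever the backing (in-memory dense, in-memory CSR sparse, or an
HDF5 file on disk).

A :class:`BlockLedger` can be attached to any store to account for the dense
block entries that are alive at any moment; it is used to assert the memory
contract in tests.
"""

from __future__ import annotations

import weakref
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
from scipy import sparse as sp


class BlockLedger:
    """Accounting of dense block entries currently resident in memory.

    Every block handed out by an instrumented store is registered here; a
    weakref finalizer deducts its size when the array is garbage collected.
    ``max_resident`` is the high-water mark of simultaneously alive entries.
    """

    def __init__(self) -> None:
        self.resident = 0
        self.max_resident = 0
        self.total_fetched = 0
        self.n_fetches = 0

    def register(self, arr: np.ndarray) -> None:
        n = int(arr.size)
        self.resident += n
        self.total_fetched += n
        self.n_fetches += 1
        if self.resident > self.max_resident:
            self.max_resident = self.resident
        weakref.finalize(arr, self._release, n)

    def _release(self, n: int) -> None:
        self.resident -= n


def _as_index(idx, n: int, axis: str) -> np.ndarray:
    if idx is None:
        return np.arange(n)
    idx = np.asarray(idx, dtype=np.intp)
    if idx.ndim != 1:
        raise ValueError(f"{axis} indices must be one-dimensional")
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError(f"{axis} index out of range (n={n})")
    return idx


def _check_names(names: Sequence[str], n: int, what: str) -> np.ndarray:
    names = np.asarray(names, dtype=object)
    if names.shape != (n,):
        raise ValueError(f"{what} must have length {n}, got {names.shape}")
    if len(set(names)) != n:
        raise ValueError(f"{what} must be unique")
    return names


class ExpressionStore:
    """Cells x genes expression matrix with named axes and block access."""

    backing: str = "abstract"

    def __init__(self, gene_names, cell_names, n_cells: int, n_genes: int):
        self.n_cells = int(n_cells)
        self.n_genes = int(n_genes)
        self.gene_names = _check_names(gene_names, self.n_genes, "gene_names")
        self.cell_names = _check_names(cell_names, self.n_cells, "cell_names")
        self.ledger: Optional[BlockLedger] = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_cells, self.n_genes)

    def fetch_block(self, cell_indices=None, gene_indices=None) -> np.ndarray:
        cells = _as_index(cell_indices, self.n_cells, "cell")
        genes = _as_index(gene_indices, self.n_genes, "gene")
        block = self._fetch(cells, genes)
        if self.ledger is not None:
            self.ledger.register(block)
        return block

    def _fetch(self, cells: np.ndarray, genes: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gene_index(self, names) -> np.ndarray:
        """Map gene names to column indices (raises on unknown names)."""
        lookup = {n: i for i, n in enumerate(self.gene_names)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown gene {e.args[0]!r}") from None


class DenseStore(ExpressionStore):
    backing = "in-memory-dense"

    def __init__(self, values, gene_names, cell_names):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        super().__init__(gene_names, cell_names, values.shape[0], values.shape[1])
        self._values = values

    def _fetch(self, cells, genes):
        return self._values[np.ix_(cells, genes)].astype(np.float64, copy=True)


class SparseStore(ExpressionStore):
    backing = "in-memory-sparse"

    def __init__(self, matrix, gene_names, cell_names):
        matrix = sp.csr_matrix(matrix, dtype=np.float64)
        if not np.all(np.isfinite(matrix.data)):
            raise ValueError("expression values must be finite")
        super().__init__(gene_names, cell_names, matrix.shape[0], matrix.shape[1])
        self._matrix = matrix

    @property
    def matrix(self) -> sp.csr_matrix:
        return self._matrix

    def _fetch(self, cells, genes):
        return np.asarray(
            self._matrix[cells][:, genes].todense(), dtype=np.float64
        )


class HDF5Store(ExpressionStore):
    """On-disk store reading CSR triplets from an HDF5 file.

    Layout: group ``/matrix`` with datasets ``data``, ``indices``, ``indptr``
    (CSR over cells x genes) and a ``shape`` attribute, plus ``/gene_names``
    and ``/cell_names`` string datasets.  ``fetch_block`` materializes only
    the requested rows; transient per-row buffers are bounded by the number
    of genes.
    """

    backing = "on-disk"

    def __init__(self, path):
        self._path = str(path)
        with h5py.File(self._path, "r") as f:
            shape = tuple(int(v) for v in f["matrix"].attrs["shape"])
            gene_names = [s.decode() if isinstance(s, bytes) else s for s in f["gene_names"][:]]
            cell_names = [s.decode() if isinstance(s, bytes) else s for s in f["cell_names"][:]]
            self._indptr = f["matrix/indptr"][:].astype(np.int64)
        super().__init__(gene_names, cell_names, shape[0], shape[1])
        self._file: Optional[h5py.File] = None

    def _h5(self) -> h5py.File:
        if self._file is None or not self._file.id.valid:
            self._file = h5py.File(self._path, "r")
        return self._file

    def close(self) -> None:
        if self._file is not None and self._file.id.valid:
            self._file.close()

    def _fetch(self, cells, genes):
        f = self._h5()
        data, indices = f["matrix/data"], f["matrix/indices"]
        block = np.zeros((cells.size, genes.size), dtype=np.float64)
        # column gather map: gene id -> output column (or -1)
        colmap = np.full(self.n_genes, -1, dtype=np.intp)
        colmap[genes] = np.arange(genes.size)
        for out_row, i in enumerate(cells):
            lo, hi = self._indptr[i], self._indptr[i + 1]
            if hi == lo:
                continue
            cols = indices[lo:hi]
            vals = data[lo:hi]
            dest = colmap[cols]
            keep = dest >= 0
            block[out_row, dest[keep]] = vals[keep]
        return block


class TransformedStore(ExpressionStore):
    """Lazy elementwise transform over a base store.

    Applies, in order: division by a per-gene factor, ``log(pseudocount + x)``
    with the convention ``log1p`` at pseudocount 1 (zeros stay zero), and
    division by a per-cell factor.  Used to preprocess on-disk stores without
    materializing the matrix; the returned blocks are transformed in place so
    no extra copies become resident.
    """

    def __init__(self, base: ExpressionStore, col_divisor=None, log_pseudocount=None,
                 row_divisor=None):
        super().__init__(base.gene_names, base.cell_names, base.n_cells, base.n_genes)
        self.base = base
        self.backing = base.backing
        self.col_divisor = None if col_divisor is None else np.asarray(col_divisor, float)
        self.log_pseudocount = log_pseudocount
        self.row_divisor = None if row_divisor is None else np.asarray(row_divisor, float)

    def fetch_block(self, cell_indices=None, gene_indices=None) -> np.ndarray:
        cells = _as_index(cell_indices, self.n_cells, "cell")
        genes = _as_index(gene_indices, self.n_genes, "gene")
        block = self.base.fetch_block(cells, genes)  # fresh dense array
        if self.col_divisor is not None:
            block /= self.col_divisor[genes][None, :]
        if self.log_pseudocount is not None:
            if self.log_pseudocount == 1.0:
                np.log1p(block, out=block)
            else:
                np.log(block + self.log_pseudocount, out=block)
        if self.row_divisor is not None:
            block /= self.row_divisor[cells][:, None]
        return block

    @property
    def ledger(self):  # share the base's ledger; blocks are transformed in place
        return self.base.ledger

    @ledger.setter
    def ledger(self, value):
        if value is not None:
            self.base.ledger = value


class SubsetStore(ExpressionStore):
    """View of a base store restricted to given cells and genes (keeps names)."""

    def __init__(self, base: ExpressionStore, cell_indices=None, gene_indices=None):
        cells = _as_index(cell_indices, base.n_cells, "cell")
        genes = _as_index(gene_indices, base.n_genes, "gene")
        super().__init__(base.gene_names[genes], base.cell_names[cells],
                         cells.size, genes.size)
        self.base = base
        self.backing = base.backing
        self._cells = cells
        self._genes = genes

    def fetch_block(self, cell_indices=None, gene_indices=None) -> np.ndarray:
        cells = _as_index(cell_indices, self.n_cells, "cell")
        genes = _as_index(gene_indices, self.n_genes, "gene")
        return self.base.fetch_block(self._cells[cells], self._genes[genes])

    @property
    def ledger(self):
        return self.base.ledger

    @ledger.setter
    def ledger(self, value):
        if value is not None:
            self.base.ledger = value


@dataclass
class LabelVector:
    """Integer class label per cell; at least two distinct classes."""

    labels: np.ndarray
    classes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("labels must be integers")
            self.labels = as_int
        self.classes = np.unique(self.labels)
        if self.classes.size < 2:
            raise ValueError("need at least two distinct classes")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_classes(self) -> int:
        return int(self.classes.size)

    def subset(self, indices) -> np.ndarray:
        """Raw label values for a cell subset (may be single-class)."""
        return self.labels[np.asarray(indices, dtype=np.intp)]


def store_from_array(values, gene_names=None, cell_names=None,
                     sparse_backing: bool = False) -> ExpressionStore:
    """Build an in-memory store, generating default axis names if omitted."""
    values = sp.csr_matrix(values) if sparse_backing else np.asarray(values, float)
    n_cells, n_genes = values.shape
    if gene_names is None:
        gene_names = [f"g{j:05d}" for j in range(n_genes)]
    if cell_names is None:
        cell_names = [f"c{i:05d}" for i in range(n_cells)]
    cls = SparseStore if sparse_backing else DenseStore
    return cls(values, gene_names, cell_names)
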