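"""Readers and writers for the supported on-disk formats.

Supported matrix formats:

* Matrix Market coordinate (``.mtx``) plus plain-text gene and cell/barcode
  name sidecars (the CellRanger-style triplet);
* dense CSV/TSV with a header row of gene names and a first column of cell
  names;
* HDF5 with CSR triplets under ``/matrix`` and name datasets (see
  :class:`~activesvm.data.HDF5Store`).

Labels load from a two-column CSV ``cell_name,label`` (header optional) or a
headerless one-label-per-line file aligned to cell order.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse as sp

from .data import (DenseStore, ExpressionStore, HDF5Store, LabelVector,
                   SparseStore)


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


_FORMATS = ("mtx", "csv", "tsv", "hdf5")


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower().lstrip(".")
    if ext in ("h5", "hdf5", "h5ad"):
        return "hdf5"
    if ext in _FORMATS:
        return ext
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


def _read_names(path: Path) -> list[str]:
    # one name per line; tab-separated sidecars keep their first field
    with open(path) as fh:
        names = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return names


def load_expression(path, format: str | None = None,
                    orientation: str = "cells_x_genes",
                    gene_file=None, cell_file=None) -> ExpressionStore:
    """Load an expression matrix into a store in cells x genes orientation.

    ``orientation`` describes the on-disk layout; the returned store is always
    cells x genes.  For ``mtx``, sidecar name files default to ``genes.tsv``
    and ``barcodes.tsv`` next to the matrix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if orientation not in ("cells_x_genes", "genes_x_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    fmt = format or _infer_format(path)

    if fmt == "mtx":
        gene_file = Path(gene_file) if gene_file else path.parent / "genes.tsv"
        cell_file = Path(cell_file) if cell_file else path.parent / "barcodes.tsv"
        for p in (gene_file, cell_file):
            if not p.exists():
                raise FileNotFoundError(f"missing sidecar name file {p}")
        try:
            mat = spio.mmread(path)
        except Exception as e:
            raise FormatError(f"malformed Matrix Market file {path}: {e}") from e
        mat = sp.csr_matrix(mat)
        if orientation == "genes_x_cells":
            mat = sp.csr_matrix(mat.T)
        genes, cells = _read_names(gene_file), _read_names(cell_file)
        if len(cells) != mat.shape[0] or len(genes) != mat.shape[1]:
            raise FormatError(
                f"sidecar/shape mismatch: matrix {mat.shape} vs "
                f"{len(cells)} cells, {len(genes)} genes")
        return SparseStore(mat, genes, cells)

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
            values = df.to_numpy(dtype=np.float64)
        except (ValueError, TypeError) as e:
            raise FormatError(f"non-numeric or malformed table {path}: {e}") from e
        if orientation == "genes_x_cells":
            df, values = df.T, values.T
        return DenseStore(values, list(df.columns), [str(i) for i in df.index])

    if fmt == "hdf5":
        store = HDF5Store(path)
        if orientation == "genes_x_cells":
            raise FormatError("HDF5 layout is defined as cells x genes")
        return store

    raise FormatError(f"unsupported format {fmt!r}")


def write_expression(store: ExpressionStore, path, format: str | None = None) -> None:
    """Write a store to disk; mtx writes the sidecar triplet next to it."""
    path = Path(path)
    fmt = format or _infer_format(path)
    full = store.fetch_block()  # fine for write-sized data

    if fmt == "mtx":
        mat = sp.coo_matrix(full)
        if np.allclose(mat.data, np.round(mat.data)):
            mat = mat.astype(np.int64)
        spio.mmwrite(path, mat, precision=17)
        (path.parent / "genes.tsv").write_text(
            "".join(f"{g}\n" for g in store.gene_names))
        (path.parent / "barcodes.tsv").write_text(
            "".join(f"{c}\n" for c in store.cell_names))
        return

    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(full, index=store.cell_names, columns=store.gene_names)
        df.to_csv(path, sep=sep)
        return

    if fmt == "hdf5":
        mat = sp.csr_matrix(full)
        with h5py.File(path, "w") as f:
            g = f.create_group("matrix")
            g.attrs["shape"] = np.array(mat.shape, dtype=np.int64)
            g.create_dataset("data", data=mat.data.astype(np.float64))
            g.create_dataset("indices", data=mat.indices.astype(np.int64))
            g.create_dataset("indptr", data=mat.indptr.astype(np.int64))
            dt = h5py.string_dtype()
            f.create_dataset("gene_names", data=np.asarray(store.gene_names, dtype=object), dtype=dt)
            f.create_dataset("cell_names", data=np.asarray(store.cell_names, dtype=object), dtype=dt)
        return

    raise FormatError(f"unsupported format {fmt!r}")


def load_labels(path, cell_names=None) -> LabelVector:
    """Load per-cell class labels.

    Two accepted layouts: two-column CSV ``cell_name,label`` (header row
    optional; rows may be in any order when ``cell_names`` is given) or a
    headerless file with one integer label per line in cell order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"empty label file {path}")

    if "," in lines[0] or "," in lines[-1]:
        rows = [ln.split(",") for ln in lines]
        if any(len(r) != 2 for r in rows):
            raise FormatError("two-column label CSV must have exactly 2 fields per row")
        try:
            int(rows[0][1])
        except ValueError:
            rows = rows[1:]  # header row
        names = [r[0] for r in rows]
        try:
            values = {n: int(v) for n, v in rows}
        except ValueError as e:
            raise FormatError(f"non-integer label: {e}") from e
        if cell_names is not None:
            missing = [n for n in cell_names if n not in values]
            if missing:
                raise FormatError(f"labels missing for cells {missing[:5]}")
            labels = np.array([values[n] for n in cell_names], dtype=np.int64)
        else:
            labels = np.array([values[n] for n in names], dtype=np.int64)
        return LabelVector(labels)

    try:
        labels = np.array([int(ln) for ln in lines], dtype=np.int64)
    except ValueError as e:
        raise FormatError(f"non-integer label: {e}") from e
    if cell_names is not None and len(labels) != len(cell_names):
        raise FormatError(
            f"{len(labels)} labels for {len(cell_names)} cells")
    return LabelVector(labels)


def write_labels(labels: LabelVector, path, cell_names=None) -> None:
    path = Path(path)
    if cell_names is None:
        path.write_text("".join(f"{v}\n" for v in labels.labels))
    else:
        rows = "".join(f"{n},{v}\n" for n, v in zip(cell_names, labels.labels))
        path.write_text("cell_name,label\n" + rows)
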