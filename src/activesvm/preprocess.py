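"""Filtering, normalization and train/test splitting.

Two preprocessing dialects are exposed as named presets:

* ``colnorm_log_l2`` — per-gene total normalization, ``log1p``, then per-cell
  L2 scaling (used for dense-ish count data);
* ``l2_only`` — per-cell L2 scaling alone (used for very large or already
  transformed matrices);
* ``none`` — raw values.

In-memory stores are materialized; on-disk stores get a lazy transformed view
so the block-access memory contract is preserved (divisors and row norms are
computed in a streaming pass over gene blocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse as sp

from .data import (DenseStore, ExpressionStore, LabelVector, SparseStore,
                   SubsetStore, TransformedStore)

PRESETS = ("colnorm_log_l2", "l2_only", "none")

_STREAM_GENES = 256  # gene-block width for streaming passes over on-disk stores


class DegenerateInputError(ValueError):
    """All-zero matrix or similarly unusable input."""


def _column_stats(store: ExpressionStore):
    """Per-gene (sum, nnz) and per-cell nnz, streaming over gene blocks."""
    col_sum = np.zeros(store.n_genes)
    col_nnz = np.zeros(store.n_genes, dtype=np.int64)
    row_nnz = np.zeros(store.n_cells, dtype=np.int64)
    for lo in range(0, store.n_genes, _STREAM_GENES):
        genes = np.arange(lo, min(lo + _STREAM_GENES, store.n_genes))
        block = store.fetch_block(None, genes)
        if np.any(block < 0):
            raise ValueError("negative values where counts were expected")
        col_sum[genes] = block.sum(axis=0)
        col_nnz[genes] = (block != 0).sum(axis=0)
        row_nnz += (block != 0).sum(axis=1)
    return col_sum, col_nnz, row_nnz


def drop_empty(store: ExpressionStore):
    """Remove all-zero gene columns and all-zero cell rows.

    Returns ``(filtered_store, kept_gene_indices, kept_cell_indices)`` where
    the index arrays map filtered coordinates back to the originals.
    """
    if isinstance(store, SparseStore):
        m = store.matrix
        col_nnz = np.diff(sp.csc_matrix(m).indptr)
        row_nnz = np.diff(m.indptr)
    elif isinstance(store, DenseStore):
        v = store.fetch_block()
        col_nnz = (v != 0).sum(axis=0)
        row_nnz = (v != 0).sum(axis=1)
    else:
        _, col_nnz, row_nnz = _column_stats(store)
    kept_genes = np.flatnonzero(col_nnz > 0)
    kept_cells = np.flatnonzero(row_nnz > 0)
    if kept_genes.size == 0 or kept_cells.size == 0:
        raise DegenerateInputError("matrix is entirely zero")
    if kept_genes.size == store.n_genes and kept_cells.size == store.n_cells:
        return store, kept_genes, kept_cells
    if isinstance(store, (DenseStore, SparseStore)):
        block = store.fetch_block(kept_cells, kept_genes)
        cls = SparseStore if isinstance(store, SparseStore) else DenseStore
        sub = cls(sp.csr_matrix(block) if cls is SparseStore else block,
                  store.gene_names[kept_genes], store.cell_names[kept_cells])
    else:
        sub = SubsetStore(store, kept_cells, kept_genes)
    return sub, kept_genes, kept_cells


def normalize_column_log(store: ExpressionStore, pseudocount: float = 1.0) -> ExpressionStore:
    """Divide each gene column by its total over cells, then log-transform.

    The transform is ``log(pseudocount + x)`` with the default pseudocount of
    1 (``log1p``), so zero entries stay zero.  Requires non-negative input.
    """
    if isinstance(store, DenseStore):
        v = store.fetch_block()
        if np.any(v < 0):
            raise ValueError("negative values: column normalization expects counts")
        col_sum = v.sum(axis=0)
        div = np.where(col_sum > 0, col_sum, 1.0)
        out = np.log(v / div[None, :] + pseudocount) if pseudocount != 1.0 \
            else np.log1p(v / div[None, :])
        return DenseStore(out, store.gene_names, store.cell_names)
    if isinstance(store, SparseStore):
        m = store.matrix.tocsc(copy=True)
        if np.any(m.data < 0):
            raise ValueError("negative values: column normalization expects counts")
        col_sum = np.asarray(m.sum(axis=0)).ravel()
        div = np.where(col_sum > 0, col_sum, 1.0)
        if pseudocount == 1.0:
            m.data /= np.repeat(div, np.diff(m.indptr))
            np.log1p(m.data, out=m.data)
            return SparseStore(m.tocsr(), store.gene_names, store.cell_names)
        dense = np.log(np.asarray(m.todense()) / div[None, :] + pseudocount)
        return DenseStore(dense, store.gene_names, store.cell_names)
    col_sum, _, _ = _column_stats(store)
    div = np.where(col_sum > 0, col_sum, 1.0)
    return TransformedStore(store, col_divisor=div, log_pseudocount=pseudocount)


def l2_normalize_rows(store: ExpressionStore) -> ExpressionStore:
    """Scale every cell row to unit Euclidean norm (zero rows are left as is)."""
    if isinstance(store, (DenseStore, SparseStore)):
        v = store.fetch_block()
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            warnings.warn("zero cell rows left unnormalized", RuntimeWarning)
        div = np.where(norms > 0, norms, 1.0)
        out = v / div[:, None]
        if isinstance(store, SparseStore):
            return SparseStore(sp.csr_matrix(out), store.gene_names, store.cell_names)
        return DenseStore(out, store.gene_names, store.cell_names)
    # streaming row norms over (possibly transformed) on-disk store
    sq = np.zeros(store.n_cells)
    for lo in range(0, store.n_genes, _STREAM_GENES):
        genes = np.arange(lo, min(lo + _STREAM_GENES, store.n_genes))
        block = store.fetch_block(None, genes)
        sq += (block ** 2).sum(axis=1)
    norms = np.sqrt(sq)
    if np.any(norms == 0):
        warnings.warn("zero cell rows left unnormalized", RuntimeWarning)
    div = np.where(norms > 0, norms, 1.0)
    if isinstance(store, TransformedStore) and store.row_divisor is None:
        return TransformedStore(store.base, store.col_divisor,
                                store.log_pseudocount, row_divisor=div)
    return TransformedStore(store, row_divisor=div)


def apply_preset(store: ExpressionStore, preset: str,
                 pseudocount: float = 1.0) -> ExpressionStore:
    if preset not in PRESETS:
        raise ValueError(f"unknown preprocessing preset {preset!r}; choose from {PRESETS}")
    if preset == "none":
        return store
    if preset == "colnorm_log_l2":
        store = normalize_column_log(store, pseudocount)
    return l2_normalize_rows(store)


@dataclass(frozen=True)
class SplitResult:
    train_cell_indices: np.ndarray
    test_cell_indices: np.ndarray


def split_train_test(n_cells: int, labels: LabelVector | None = None,
                     train_fraction: float = 0.8, seed=None,
                     stratified: bool = False) -> SplitResult:
    """Uniform random train/test split of cells without replacement.

    ``|train| = round(train_fraction * n_cells)``.  Warns when a class is
    absent from the training split (the classifier cannot learn it).  The
    optional stratified mode splits each class separately.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_fraction * n_cells))
    if stratified:
        if labels is None:
            raise ValueError("stratified split requires labels")
        train_parts = []
        for z in labels.classes:
            members = np.flatnonzero(labels.labels == z)
            k = int(round(train_fraction * members.size))
            train_parts.append(rng.permutation(members)[:k])
        train = np.sort(np.concatenate(train_parts))
    else:
        perm = rng.permutation(n_cells)
        train = np.sort(perm[:n_train])
    mask = np.zeros(n_cells, dtype=bool)
    mask[train] = True
    test = np.flatnonzero(~mask)
    if labels is not None:
        present = set(np.unique(labels.labels[train]).tolist())
        missing = [z for z in labels.classes.tolist() if z not in present]
        if missing:
            warnings.warn(f"classes {missing} absent from training split", RuntimeWarning)
    return SplitResult(train, test)
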