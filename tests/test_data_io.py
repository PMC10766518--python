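"""Stores, file formats, filtering, normalization and splitting."""

import numpy as np
import pytest
from scipy import sparse as sp

from activesvm import (BlockLedger, DenseStore, FormatError, LabelVector,
                       SparseStore, load_expression, load_labels,
                       write_expression, write_labels)
from activesvm.data import HDF5Store, store_from_array
from activesvm.preprocess import (DegenerateInputError, apply_preset,
                                  drop_empty, l2_normalize_rows,
                                  normalize_column_log, split_train_test)


class TestStores:
    def test_dense_block_access(self, small_store):
        assert small_store.shape == (2, 3)
        full = small_store.fetch_block()
        assert np.count_nonzero(full) == 3
        np.testing.assert_array_equal(full, [[1, 0, 2], [0, 3, 0]])
        # single cell x single gene and empty gene list
        assert small_store.fetch_block([1], [1]) == np.array([[3.0]])
        assert small_store.fetch_block([0, 1], []).shape == (2, 0)

    def test_sparse_dense_parity(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(1.0, size=(7, 5)).astype(float)
        d = store_from_array(v)
        s = store_from_array(v, sparse_backing=True)
        cells, genes = [5, 0, 3], [4, 1]
        np.testing.assert_array_equal(d.fetch_block(cells, genes),
                                      s.fetch_block(cells, genes))

    def test_out_of_range_and_validation(self, small_store):
        with pytest.raises(IndexError):
            small_store.fetch_block([5], None)
        with pytest.raises(IndexError):
            small_store.fetch_block(None, [-1])
        with pytest.raises(ValueError, match="finite"):
            DenseStore(np.array([[np.nan, 1.0]]), ["a", "b"], ["c"])
        with pytest.raises(ValueError, match="unique"):
            DenseStore(np.ones((1, 2)), ["a", "a"], ["c"])

    def test_gene_index_lookup(self, small_store):
        np.testing.assert_array_equal(small_store.gene_index(["gC", "gA"]), [2, 0])
        with pytest.raises(KeyError):
            small_store.gene_index(["nope"])

    def test_block_ledger_accounting(self, small_store):
        ledger = BlockLedger()
        small_store.ledger = ledger
        b1 = small_store.fetch_block()
        assert ledger.resident == 6 and ledger.max_resident == 6
        b2 = small_store.fetch_block([0], None)
        assert ledger.resident == 9
        del b1, b2
        assert ledger.resident == 0 and ledger.max_resident == 9


class TestFileFormats:
    @pytest.mark.parametrize("fmt", ["mtx", "csv", "tsv", "hdf5"])
    def test_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(1)
        counts = rng.poisson(0.8, size=(6, 9)).astype(float)
        store = store_from_array(counts)
        ext = {"mtx": "mtx", "csv": "csv", "tsv": "tsv", "hdf5": "h5"}[fmt]
        path = tmp_path / f"m.{ext}"
        write_expression(store, path, fmt)
        back = load_expression(path, fmt)
        np.testing.assert_allclose(back.fetch_block(), counts, atol=1e-12)
        assert list(back.gene_names) == list(store.gene_names)
        assert list(back.cell_names) == list(store.cell_names)

    def test_float_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(4, 3)) ** 2
        store = store_from_array(vals)
        for fmt, name in [("csv", "m.csv"), ("hdf5", "m.h5")]:
            write_expression(store, tmp_path / name, fmt)
            back = load_expression(tmp_path / name, fmt)
            np.testing.assert_allclose(back.fetch_block(), vals, atol=1e-12)

    def test_mtx_genes_x_cells_orientation(self, tmp_path):
        counts = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 0.0]])  # genes x cells
        sp_m = sp.coo_matrix(counts)
        from scipy.io import mmwrite
        mmwrite(tmp_path / "m.mtx", sp_m.astype(np.int64))
        (tmp_path / "genes.tsv").write_text("g1\ng2\ng3\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        store = load_expression(tmp_path / "m.mtx", "mtx",
                                orientation="genes_x_cells")
        assert store.shape == (2, 3)
        np.testing.assert_array_equal(store.fetch_block(), counts.T)

    def test_malformed_mtx_rejected(self, tmp_path):
        (tmp_path / "m.mtx").write_text(
            "%%MatrixMarket matrix coordinate integer general\n"
            "2 3 5\n1 1 1\n1 3 2\n2 2 3\n2 3 9\n")  # header says 5, gives 4
        (tmp_path / "genes.tsv").write_text("g1\ng2\ng3\n")
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        with pytest.raises(FormatError):
            load_expression(tmp_path / "m.mtx", "mtx")

    def test_sidecar_shape_mismatch(self, tmp_path):
        from scipy.io import mmwrite
        mmwrite(tmp_path / "m.mtx", sp.coo_matrix(np.eye(2)).astype(np.int64))
        (tmp_path / "genes.tsv").write_text("g1\ng2\ng3\n")  # 3 names, 2 cols
        (tmp_path / "barcodes.tsv").write_text("c1\nc2\n")
        with pytest.raises(FormatError, match="mismatch"):
            load_expression(tmp_path / "m.mtx", "mtx")

    def test_missing_file_and_nonnumeric(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_expression(tmp_path / "absent.csv", "csv")
        (tmp_path / "bad.csv").write_text("cell,g1\nc1,abc\n")
        with pytest.raises((FormatError, ValueError)):
            load_expression(tmp_path / "bad.csv", "csv")

    def test_labels_two_column_and_plain(self, tmp_path):
        lv = LabelVector(np.array([0, 1, 1]))
        write_labels(lv, tmp_path / "plain.txt")
        assert np.array_equal(load_labels(tmp_path / "plain.txt").labels, [0, 1, 1])
        write_labels(lv, tmp_path / "named.csv", cell_names=["a", "b", "c"])
        # out-of-order lookup by cell name
        back = load_labels(tmp_path / "named.csv", cell_names=["c", "a", "b"])
        assert np.array_equal(back.labels, [1, 0, 1])

    def test_label_vector_needs_two_classes(self):
        with pytest.raises(ValueError, match="two distinct"):
            LabelVector(np.zeros(5, dtype=int))


class TestDropEmpty:
    def test_zero_gene_column_removed(self):
        v = np.array([[1.0, 0.0, 2.0], [3.0, 0.0, 1.0]])
        store = store_from_array(v)
        sub, genes, cells = drop_empty(store)
        np.testing.assert_array_equal(genes, [0, 2])
        np.testing.assert_array_equal(cells, [0, 1])
        np.testing.assert_array_equal(sub.fetch_block(), [[1, 2], [3, 1]])
        assert list(sub.gene_names) == ["g00000", "g00002"]

    def test_identity_when_nothing_empty(self):
        store = store_from_array(np.ones((3, 2)))
        sub, genes, cells = drop_empty(store)
        np.testing.assert_array_equal(genes, [0, 1])
        np.testing.assert_array_equal(cells, [0, 1, 2])

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            drop_empty(store_from_array(np.zeros((2, 2))))

    def test_sparse_backing(self):
        v = np.array([[0.0, 1.0], [0.0, 0.0], [0.0, 2.0]])
        sub, genes, cells = drop_empty(store_from_array(v, sparse_backing=True))
        np.testing.assert_array_equal(genes, [1])
        np.testing.assert_array_equal(cells, [0, 2])


class TestNormalization:
    def test_column_normalization_closed_form(self):
        store = store_from_array(np.array([[1.0], [3.0]]), gene_names=["g"],
                                 cell_names=["a", "b"])
        out = normalize_column_log(store).fetch_block()
        np.testing.assert_allclose(out.ravel(), np.log1p([0.25, 0.75]))

    def test_zero_stays_zero_and_negatives_rejected(self):
        store = store_from_array(np.array([[0.0, 1.0], [2.0, 1.0]]))
        out = normalize_column_log(store).fetch_block()
        assert out[0, 0] == 0.0
        with pytest.raises(ValueError, match="negative"):
            normalize_column_log(store_from_array(np.array([[-1.0, 1.0]])))

    def test_column_sums_invariant(self):
        rng = np.random.default_rng(3)
        store = store_from_array(rng.poisson(2.0, (20, 6)) + 1.0)
        out = normalize_column_log(store).fetch_block()
        np.testing.assert_allclose((np.exp(out) - 1).sum(axis=0),
                                   np.ones(6), atol=1e-9)

    def test_l2_rows_closed_form(self):
        store = store_from_array(np.array([[3.0, 4.0], [0.6, 0.8]]))
        out = l2_normalize_rows(store).fetch_block()
        np.testing.assert_allclose(out, [[0.6, 0.8], [0.6, 0.8]], atol=1e-12)

    def test_l2_zero_row_warns_and_passes_through(self):
        store = store_from_array(np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.warns(RuntimeWarning, match="zero cell rows"):
            out = l2_normalize_rows(store).fetch_block()
        np.testing.assert_array_equal(out[0], [0.0, 0.0])

    def test_preset_chain_gives_unit_rows(self):
        rng = np.random.default_rng(4)
        store = store_from_array(rng.poisson(2.0, (15, 8)) + 1.0)
        out = apply_preset(store, "colnorm_log_l2").fetch_block()
        np.testing.assert_allclose(np.linalg.norm(out, axis=1), 1.0, atol=1e-9)
        with pytest.raises(ValueError, match="preset"):
            apply_preset(store, "bogus")


class TestOnDiskStore:
    def test_hdf5_block_parity_and_lazy_preprocessing(self, tmp_path):
        rng = np.random.default_rng(5)
        counts = rng.poisson(1.5, size=(30, 40)).astype(float)
        counts[:, 7] = 0.0  # an empty gene to exercise filtering
        counts[3] = 0.0
        dense = store_from_array(counts)
        write_expression(dense, tmp_path / "m.h5", "hdf5")
        disk = HDF5Store(tmp_path / "m.h5")
        assert disk.backing == "on-disk"
        cells, genes = [0, 9, 22], [1, 7, 39]
        np.testing.assert_array_equal(disk.fetch_block(cells, genes),
                                      dense.fetch_block(cells, genes))
        # the whole preprocessing chain, lazy vs materialized
        d_sub, dg, dc = drop_empty(dense)
        k_sub, kg, kc = drop_empty(disk)
        np.testing.assert_array_equal(dg, kg)
        np.testing.assert_array_equal(dc, kc)
        lazy = apply_preset(k_sub, "colnorm_log_l2")
        mat = apply_preset(d_sub, "colnorm_log_l2")
        np.testing.assert_allclose(lazy.fetch_block(), mat.fetch_block(),
                                   atol=1e-12)
        disk.close()


class TestSplit:
    def test_split_sizes_and_determinism(self):
        labels = LabelVector(np.repeat([0, 1], 5))
        s1 = split_train_test(10, labels, 0.8, seed=11)
        s2 = split_train_test(10, labels, 0.8, seed=11)
        assert s1.train_cell_indices.size == 8
        assert s1.test_cell_indices.size == 2
        assert np.intersect1d(s1.train_cell_indices, s1.test_cell_indices).size == 0
        union = np.union1d(s1.train_cell_indices, s1.test_cell_indices)
        np.testing.assert_array_equal(union, np.arange(10))
        np.testing.assert_array_equal(s1.train_cell_indices, s2.train_cell_indices)
        assert not np.array_equal(
            split_train_test(10, labels, 0.8, seed=12).train_cell_indices,
            s1.train_cell_indices)

    def test_bad_fraction_rejected(self):
        for frac in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                split_train_test(10, None, frac, seed=0)

    def test_missing_class_warns(self):
        labels = LabelVector(np.array([0] * 9 + [1]))
        with pytest.warns(RuntimeWarning, match="absent"):
            for seed in range(20):  # some seed puts the singleton in test
                split_train_test(10, labels, 0.8, seed=seed)

    def test_stratified_keeps_class_shares(self):
        labels = LabelVector(np.repeat([0, 1, 2], [50, 30, 20]))
        s = split_train_test(100, labels, 0.8, seed=1, stratified=True)
        tr = labels.labels[s.train_cell_indices]
        assert [int((tr == z).sum()) for z in (0, 1, 2)] == [40, 24, 16]
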