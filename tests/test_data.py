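"""Dataset containers, format round-trips, preprocessing transforms,
and fold splitting."""

import numpy as np
import pandas as pd
import pytest

from unitednet.data import (
    ModalityMatrix,
    MultiModalDataset,
    binarize,
    load_dataset,
    load_modality,
    normalize_log1p,
    save_modality,
    select_top_variable,
    split_folds,
    standardize_cells,
    standardize_features,
)


def _write_csv(path, values, cells, feats):
    pd.DataFrame(values, index=cells, columns=feats).to_csv(path)


class TestContainers:
    def test_feature_name_count_must_match(self):
        with pytest.raises(ValueError, match="feature names"):
            ModalityMatrix("m", np.zeros((2, 3)), ["a", "b"])

    def test_duplicate_feature_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ModalityMatrix("m", np.zeros((2, 2)), ["a", "a"])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ModalityMatrix("m", np.array([[np.nan, 1.0]]), ["a", "b"])

    def test_binary_flag_enforced(self):
        with pytest.raises(ValueError, match="binary"):
            ModalityMatrix("m", np.array([[0.5, 1.0]]), ["a", "b"], is_binary=True)

    def test_row_count_alignment(self, tiny_modality):
        other = ModalityMatrix("o", np.zeros((3, 2)), ["x", "y"])
        with pytest.raises(ValueError, match="cells"):
            MultiModalDataset([tiny_modality, other])

    def test_labels_validated(self, tiny_modality):
        with pytest.raises(ValueError, match="1..K|{1..K}"):
            MultiModalDataset([tiny_modality], labels=np.array([0, 1]))


@pytest.mark.parametrize("fmt", ["csv", "tsv", "mtx", "h5ad"])
def test_round_trip_preserves_values_and_names(tmp_path, rng, fmt):
    m = ModalityMatrix(
        "m", rng.standard_normal((6, 4)), [f"g{j}" for j in range(4)]
    )
    cells = [f"c{i}" for i in range(6)]
    path = tmp_path / f"m.{fmt}"
    save_modality(m, path, cells, fmt=fmt)
    back, back_cells = load_modality(path, fmt=fmt)
    np.testing.assert_allclose(back.values, m.values, atol=1e-12)
    assert back.feature_names == m.feature_names
    assert back_cells == cells


class TestLoadDataset:
    def test_identity_alignment(self, tmp_path, rng):
        cells = [f"c{i}" for i in range(5)]
        _write_csv(tmp_path / "a.csv", rng.standard_normal((5, 3)), cells, list("xyz"))
        _write_csv(tmp_path / "b.csv", rng.standard_normal((5, 2)), cells, list("uv"))
        ds = load_dataset({"a": tmp_path / "a.csv", "b": tmp_path / "b.csv"})
        assert ds.n_cells == 5 and ds.n_modalities == 2

    def test_reorders_by_shared_identifiers(self, tmp_path, rng):
        cells = [f"c{i}" for i in range(5)]
        a = rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 2))
        _write_csv(tmp_path / "a.csv", a, cells, list("xyz"))
        _write_csv(tmp_path / "b.csv", b, cells[::-1], list("uv"))
        ds = load_dataset({"a": tmp_path / "a.csv", "b": tmp_path / "b.csv"})
        np.testing.assert_allclose(ds.modality("b").values, b[::-1])

    def test_mismatched_cells_name_offender(self, tmp_path, rng):
        _write_csv(tmp_path / "a.csv", rng.standard_normal((3, 2)), ["c0", "c1", "c2"], ["x", "y"])
        _write_csv(tmp_path / "b.csv", rng.standard_normal((3, 2)), ["c0", "c1", "c9"], ["u", "v"])
        with pytest.raises(ValueError, match="'b'"):
            load_dataset({"a": tmp_path / "a.csv", "b": tmp_path / "b.csv"})

    def test_non_numeric_entry_reported(self, tmp_path):
        (tmp_path / "a.csv").write_text("cell,x,y\nc0,1,2\nc1,oops,4\n")
        with pytest.raises(ValueError, match="c1.*'x'"):
            load_modality(tmp_path / "a.csv")


class TestStandardizeCells:
    def test_derived_row(self):
        m = ModalityMatrix("m", np.array([[1.0, 2.0, 3.0]]), list("abc"))
        out = standardize_cells(m)
        np.testing.assert_allclose(
            out.values[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_idempotent_on_standardized(self, rng):
        m = ModalityMatrix("m", rng.standard_normal((4, 6)), [f"f{j}" for j in range(6)])
        once = standardize_cells(m)
        twice = standardize_cells(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_row_statistics_property(self, rng):
        m = ModalityMatrix("m", rng.standard_normal((8, 20)) * 3 + 1, [f"f{j}" for j in range(20)])
        out = standardize_cells(m)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        assert np.abs(out.values.std(axis=1) - 1).max() < 1e-10

    def test_constant_row_identified(self):
        m = ModalityMatrix("m", np.array([[1.0, 2.0], [5.0, 5.0]]), ["a", "b"])
        with pytest.raises(ValueError, match="cell 1"):
            standardize_cells(m)

    def test_feature_wise_alternative(self, rng):
        m = ModalityMatrix("m", rng.standard_normal((30, 4)), list("abcd"))
        out = standardize_features(m)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10


class TestNormalizeLog1p:
    def test_totals_scaled_to_median(self):
        vals = np.array([[10.0, 0.0], [10.0, 10.0], [10.0, 20.0]])
        out = normalize_log1p(ModalityMatrix("m", vals, ["a", "b"]))
        totals = np.expm1(out.values).sum(axis=1)
        np.testing.assert_allclose(totals, [20.0, 20.0, 20.0], atol=1e-9)

    def test_zero_maps_to_zero(self):
        out = normalize_log1p(ModalityMatrix("m", np.array([[0.0, 4.0]]), ["a", "b"]))
        assert out.values[0, 0] == 0.0

    def test_single_row_hand_value(self):
        out = normalize_log1p(ModalityMatrix("m", np.array([[1.0, 1.0]]), ["a", "b"]))
        np.testing.assert_allclose(out.values[0], np.log(2.0), atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            normalize_log1p(ModalityMatrix("m", np.array([[-1.0, 2.0]]), ["a", "b"]))


class TestBinarize:
    def test_rule(self):
        out = binarize(ModalityMatrix("m", np.array([[0.0, 3.0, 0.5]]), list("abc")))
        np.testing.assert_array_equal(out.values, [[0.0, 1.0, 1.0]])
        assert out.is_binary

    def test_idempotent(self, rng):
        m = binarize(ModalityMatrix("m", rng.poisson(0.5, (5, 4)).astype(float), list("abcd")))
        np.testing.assert_array_equal(binarize(m).values, m.values)


class TestSelectTopVariable:
    def test_variance_ranking(self):
        vals = np.column_stack(
            [np.ones(4), np.arange(4.0), np.arange(4.0) * 2]
        )
        out = select_top_variable(ModalityMatrix("m", vals, list("abc")), 2)
        assert out.feature_names == ["b", "c"]

    def test_identity_when_all_kept(self, tiny_modality):
        out = select_top_variable(tiny_modality, 3)
        np.testing.assert_array_equal(out.values, tiny_modality.values)

    @pytest.mark.parametrize("bad", [0, 4])
    def test_out_of_range_rejected(self, tiny_modality, bad):
        with pytest.raises(ValueError):
            select_top_variable(tiny_modality, bad)


class TestSplitFolds:
    def _dataset(self, n, batches=None):
        m = ModalityMatrix("m", np.zeros((n, 2)), ["a", "b"])
        return MultiModalDataset([m], batch_ids=batches)

    def test_balanced_sizes(self):
        split = split_folds(self._dataset(10), k=5, seed=0)
        assert sorted(np.bincount(split.fold_assignment)[1:]) == [2] * 5

    def test_deterministic(self):
        d = self._dataset(23)
        a = split_folds(d, 4, seed=7).fold_assignment
        b = split_folds(d, 4, seed=7).fold_assignment
        np.testing.assert_array_equal(a, b)

    def test_by_batch_keeps_batches_whole(self):
        batches = np.repeat([f"b{i}" for i in range(13)], 3)
        d = self._dataset(39, batches)
        split = split_folds(d, 13, mode="by_batch", seed=1)
        for b in np.unique(batches):
            assert len(np.unique(split.fold_assignment[batches == b])) == 1
        # 13 batches into 13 folds: one batch per fold
        assert len(np.unique(split.fold_assignment)) == 13

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            split_folds(self._dataset(3), k=5)
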