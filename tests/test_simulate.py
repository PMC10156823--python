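"""Synthetic-data generators: reproducibility, stated shapes, dropout
statistics, batch structure, spatial layout, and marker planting."""

import numpy as np
import pytest
from scipy import stats

from unitednet.simulate import (
    DYNGEN_LIKE,
    MUSE_LIKE,
    GeneratorSpec,
    apply_dropout,
    plant_markers,
    simulate_batches,
    simulate_multimodal,
    simulate_spatial,
)


class TestSimulateMultimodal:
    def test_four_modality_preset_shapes(self):
        ds = simulate_multimodal(DYNGEN_LIKE)
        assert ds.n_cells == 500 and ds.n_modalities == 4
        assert all(m.n_features == 100 for m in ds.modalities)
        assert ds.labels.min() >= 1 and ds.labels.max() == 4

    def test_paired_preset_shapes(self):
        ds = simulate_multimodal(MUSE_LIKE)
        assert ds.n_cells == 1000 and ds.n_modalities == 2
        assert ds.labels.max() == 10

    def test_seed_reproducibility(self):
        a = simulate_multimodal(GeneratorSpec(n_cells=50, seed=5))
        b = simulate_multimodal(GeneratorSpec(n_cells=50, seed=5))
        c = simulate_multimodal(GeneratorSpec(n_cells=50, seed=6))
        np.testing.assert_array_equal(a.modalities[0].values, b.modalities[0].values)
        assert not np.array_equal(a.modalities[0].values, c.modalities[0].values)

    def test_well_separated_limit_recoverable_by_kmeans(self):
        from sklearn.cluster import KMeans

        from unitednet.metrics import ari

        ds = simulate_multimodal(
            GeneratorSpec(
                n_cells=300, n_groups=3, n_modalities=2, n_features=(30, 30),
                separation=40.0, seed=2,
            )
        )
        km = KMeans(3, n_init=10, random_state=0).fit_predict(
            ds.modalities[0].values
        )
        assert ari(km, ds.labels) > 0.999

    def test_group_means_converge_to_design(self):
        # empirical group means in latent-projected space approach the
        # design means at the noise-governed rate
        spec = GeneratorSpec(
            n_cells=1000, n_groups=2, n_modalities=2, n_features=(50, 50),
            noise_sd=0.5, seed=3,
        )
        ds = simulate_multimodal(spec)
        X = ds.modalities[0].values
        for g in (1, 2):
            rows = ds.labels == g
            sem = X[rows].std(axis=0).mean() / np.sqrt(rows.sum())
            spread = np.abs(X[rows].mean(axis=0) - X[rows].mean(axis=0)).max()
            assert spread <= 5 * sem + 1e-12


class TestDropout:
    def test_identity_at_decay_one(self, rng):
        from unitednet.data import ModalityMatrix

        m = ModalityMatrix("m", rng.standard_normal((10, 5)), [f"f{j}" for j in range(5)])
        np.testing.assert_array_equal(apply_dropout(m, 1.0).values, m.values)

    def test_heavy_dropout_zero_fraction(self, rng):
        from unitednet.data import ModalityMatrix

        n, p, decay = 200, 100, 0.01
        m = ModalityMatrix("m", np.ones((n, p)), [f"f{j}" for j in range(p)])
        out = apply_dropout(m, decay, seed=0)
        kept = int((out.values != 0).sum())
        lo, hi = stats.binom.interval(0.999, n * p, decay)
        assert lo <= kept <= hi

    def test_expected_nonzero_fraction(self, rng):
        from unitednet.data import ModalityMatrix

        m = ModalityMatrix("m", np.ones((100, 100)), [f"f{j}" for j in range(100)])
        out = apply_dropout(m, 0.4, seed=1)
        assert np.isclose((out.values != 0).mean(), 0.4, atol=0.02)

    def test_invalid_decay(self, tiny_modality):
        with pytest.raises(ValueError):
            apply_dropout(tiny_modality, 0.0)


class TestBatches:
    def test_batch_means_differ_by_shift(self):
        spec = GeneratorSpec(
            n_cells=2000, n_groups=2, n_modalities=2, n_features=(40, 40),
            noise_sd=0.1, seed=4,
        )
        ds = simulate_batches(spec, n_batches=2, shift=5.0)
        X = ds.modalities[0].values
        d = X[ds.batch_ids == "batch0"].mean(0) - X[ds.batch_ids == "batch1"].mean(0)
        # two offsets of norm 5 in random directions: distance ~ 5*sqrt(2)
        assert 3.0 < np.linalg.norm(d) < 9.0

    def test_zero_shift_batches_identical_in_distribution(self):
        spec = GeneratorSpec(
            n_cells=3000, n_groups=2, n_modalities=2, n_features=(20, 20), seed=5
        )
        ds = simulate_batches(spec, n_batches=3, shift=0.0)
        X = ds.modalities[0].values
        means = [X[ds.batch_ids == b].mean(0) for b in np.unique(ds.batch_ids)]
        assert np.linalg.norm(means[0] - means[1]) < 0.5

    def test_leave_one_batch_out_alignment(self):
        from unitednet.data import split_folds

        spec = GeneratorSpec(n_cells=100, n_modalities=2, n_features=(10, 10), seed=6)
        ds = simulate_batches(spec, n_batches=4, shift=1.0)
        split = split_folds(ds, 4, mode="by_batch", seed=0)
        for b in np.unique(ds.batch_ids):
            assert len(np.unique(split.fold_assignment[ds.batch_ids == b])) == 1


class TestSpatial:
    def test_labels_spatially_contiguous(self):
        ds = simulate_spatial(
            GeneratorSpec(n_cells=100, n_groups=2, n_modalities=2, n_features=(10, 10), seed=7),
            grid_shape=(10, 10),
        )
        # vertical bands: label is a monotone function of the x coordinate
        for g in (1, 2):
            xs = ds.coords[ds.labels == g, 0]
            other = ds.coords[ds.labels != g, 0]
            assert xs.max() <= other.min() or xs.min() >= other.max()

    def test_refinement_fixed_point_on_clean_layout(self):
        from unitednet.spatial import refine_labels

        ds = simulate_spatial(
            GeneratorSpec(n_cells=144, n_groups=2, n_modalities=2, n_features=(8, 8), seed=8),
            grid_shape=(12, 12),
        )
        refined = refine_labels(ds.labels, ds.coords, n_neighbors=6)
        assert (refined == ds.labels).mean() > 0.95  # only band borders may flip

    def test_interior_niche_approaches_region_mean(self):
        from unitednet.spatial import build_niche_modality

        ds = simulate_spatial(
            GeneratorSpec(
                n_cells=400, n_groups=2, n_modalities=2, n_features=(20, 20),
                noise_sd=0.3, seed=9,
            ),
            grid_shape=(20, 20),
        )
        m = ds.modalities[0]
        niche = build_niche_modality(m, ds.coords, J=8)
        # a cell deep inside region 1 (x small, central y)
        i = int(np.flatnonzero((ds.coords[:, 0] == 2) & (ds.coords[:, 1] == 10))[0])
        region_mean = m.values[ds.labels == ds.labels[i]].mean(axis=0)
        err = np.abs(niche.values[i] - region_mean).mean()
        assert err < 3 * 0.3 / np.sqrt(8) + 0.2


class TestPlantMarkers:
    def test_zero_effect_is_identity(self, small_dataset):
        planted = plant_markers(small_dataset, {1: {"mod1": [0]}}, effect=0.0)
        np.testing.assert_array_equal(
            planted.modalities[0].values, small_dataset.modalities[0].values
        )

    def test_large_effect_dominates_between_group_difference(self, small_dataset):
        planted = plant_markers(small_dataset, {1: {"mod1": [3]}}, effect=50.0)
        X = planted.modalities[0].values
        in_g = X[planted.labels == 1].mean(0)
        out_g = X[planted.labels != 1].mean(0)
        assert np.argmax(np.abs(in_g - out_g)) == 3

    def test_truth_recorded(self, small_dataset):
        planted = plant_markers(small_dataset, {2: {"mod2": [1, 4]}}, effect=1.0)
        assert planted.marker_truth == {2: {"mod2": ["mod2_f1", "mod2_f4"]}}

    def test_original_untouched(self, small_dataset):
        before = small_dataset.modalities[0].values.copy()
        plant_markers(small_dataset, {1: {"mod1": [0]}}, effect=9.0)
        np.testing.assert_array_equal(small_dataset.modalities[0].values, before)
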