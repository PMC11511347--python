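"""K-means shift clustering, elbow selection and noise-cluster removal."""

import numpy as np
import pytest
from sklearn.base import clone

from sersml import (
    KMeansShiftSelector,
    apply_mask,
    build_shift_matrix,
    elbow_select_k,
    identify_noise_clusters,
    kmeans_shifts,
    select_features,
)
from sersml.feature_selection import FeatureMask, between_group_shift_scores

from conftest import banded_shift_matrix, brute_force_kmeans, canonical_partition


class TestBuildShiftMatrix:
    def test_shape_is_transposed(self):
        X = np.random.default_rng(0).normal(size=(70, 151))
        M = build_shift_matrix(X)
        assert M.shape == (151, 70)
        assert np.array_equal(M[3], X[:, 3])

    def test_single_spectrum(self):
        M = build_shift_matrix(np.ones((1, 10)))
        assert M.shape == (10, 1)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_shift_matrix(np.empty((0, 10)))


class TestKMeansShifts:
    def test_two_identical_blocks_perfect_partition(self):
        M = np.vstack([np.zeros((5, 3)), np.full((4, 3), 10.0)])
        res = kmeans_shifts(M, 2, seed=0)
        assert res.wcss == pytest.approx(0.0, abs=1e-9)
        assert len(set(res.labels[:5])) == 1 and len(set(res.labels[5:])) == 1
        assert res.labels[0] != res.labels[5]

    def test_singleton_clusters_zero_wcss(self):
        M = np.random.default_rng(1).normal(size=(6, 2))
        res = kmeans_shifts(M, 6, seed=0)
        assert res.wcss == pytest.approx(0.0, abs=1e-9)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError):
            kmeans_shifts(np.zeros((4, 2)), 5)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_brute_force_partition(self, trial):
        """On tiny instances the best-of-restarts k-means must equal the
        exhaustively enumerated minimum-WCSS partition."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        M = rng.normal(size=(n, 2))
        oracle_labels, oracle_wcss = brute_force_kmeans(M, k)
        res = kmeans_shifts(M, k, seed=trial, n_init=20)
        assert res.wcss == pytest.approx(oracle_wcss, rel=1e-9, abs=1e-9)
        assert canonical_partition(res.labels) == canonical_partition(oracle_labels)

    def test_wcss_non_increasing_in_k(self):
        M = np.random.default_rng(2).normal(size=(30, 5))
        wcss = [kmeans_shifts(M, k, seed=0).wcss for k in range(1, 9)]
        assert all(b <= a + 1e-9 for a, b in zip(wcss, wcss[1:]))


class TestElbow:
    def test_four_separated_groups_recovered(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [50, 0], [0, 50], [50, 50]], dtype=float)
        M = np.vstack([c + rng.normal(0, 0.5, size=(10, 2)) for c in centers])
        k_star, wcss = elbow_select_k(M, k_max=10, seed=0)
        assert k_star == 4
        assert wcss.shape == (10,)

    def test_two_point_masses(self):
        M = np.vstack([np.zeros((6, 2)), np.full((6, 2), 5.0)])
        k_star, _ = elbow_select_k(M, k_max=6, seed=0)
        assert k_star == 2

    def test_degenerate_flat_curve_ties_to_smallest_k(self):
        # identical rows: wcss is 0 for every k -> tie resolves to k = 1
        M = np.ones((8, 3))
        k_star, _ = elbow_select_k(M, k_max=5, seed=0)
        assert k_star == 1

    def test_k_max_validation(self):
        with pytest.raises(ValueError):
            elbow_select_k(np.zeros((4, 2)), k_max=10)
        with pytest.raises(ValueError):
            elbow_select_k(np.zeros((4, 2)), k_max=1)

    def test_banded_construction_gives_four_clusters(self):
        M = banded_shift_matrix(seed=0)
        k_star, _ = elbow_select_k(M, k_max=10, seed=0)
        assert k_star == 4


class TestNoiseClusterIdentification:
    def _assignment(self, labels, k):
        from sersml.feature_selection import ClusterAssignment

        return ClusterAssignment(k=k, labels=np.asarray(labels), centroids=np.zeros((k, 0)), wcss=0.0)

    def test_uninformative_cluster_identified(self):
        """Shifts whose intensities are identical across groups score zero
        between-group variance and are flagged as noise."""
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3, 4], 5)
        n = y.size
        X = np.zeros((n, 6))
        X[:, :3] = y[:, None] * 2.0 + rng.normal(0, 0.01, (n, 3))  # group-dependent
        X[:, 3:] = rng.normal(0, 1.0, (n, 3))  # pure noise, same law for all groups
        assignment = self._assignment([0, 0, 0, 1, 1, 1], k=2)
        dropped = identify_noise_clusters(assignment, X, y, n_drop=1)
        assert dropped == (1,)

    def test_n_drop_zero_returns_empty(self):
        assignment = self._assignment([0, 1, 0, 1], k=2)
        assert identify_noise_clusters(assignment, np.zeros((4, 4)), np.array([1, 1, 2, 2]), 0) == ()

    def test_n_drop_ge_k_rejected(self):
        assignment = self._assignment([0, 1, 0, 1], k=2)
        with pytest.raises(ValueError):
            identify_noise_clusters(assignment, np.zeros((4, 4)), np.array([1, 1, 2, 2]), 2)

    def test_tie_breaks_to_smallest_cluster_id(self):
        # statistically identical clusters: identical columns => equal scores
        y = np.array([1, 1, 2, 2])
        X = np.tile(y[:, None] * 1.0, (1, 4))
        assignment = self._assignment([1, 0, 1, 0], k=2)
        dropped = identify_noise_clusters(assignment, X, y, n_drop=1)
        assert dropped == (0,)

    def test_between_group_scores_zero_for_identical_groups(self):
        X = np.tile(np.arange(5.0), (6, 1))
        y = np.array([1, 1, 2, 2, 3, 3])
        assert np.allclose(between_group_shift_scores(X, y), 0.0)


class TestSelectFeatures:
    def test_band_shifts_retained_on_synthetic_training_half(self, small_preprocessed):
        pre = small_preprocessed
        half = pre.subset(range(0, pre.n_spectra, 2))
        mask = select_features(half.intensities, half.y, half.shifts, seed=0)
        for center in (730.0, 1330.0, 1460.0):
            assert np.any(np.abs(mask.selected_shifts - center) <= 10.0), center

    def test_n_drop_zero_keeps_all_shifts(self, small_preprocessed):
        pre = small_preprocessed
        mask = select_features(pre.intensities, pre.y, pre.shifts, n_drop=0, seed=0)
        assert mask.selected_idx.size == pre.n_shifts

    def test_forced_drop_even_when_all_shifts_informative(self):
        """n_drop is a forced count, not a threshold: the lowest-scoring
        cluster is dropped even if every shift carries signal."""
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3, 4], 4)
        X = np.column_stack([y * (j + 1.0) for j in range(8)]) + rng.normal(0, 0.01, (16, 8))
        mask = select_features(X, y, np.arange(8.0), k_max=4, n_drop=1, seed=0)
        assert len(mask.dropped_clusters) == 1
        assert mask.selected_idx.size < 8

    def test_mask_independent_of_test_half(self, small_preprocessed):
        """Leakage guard: replacing the held-out half leaves the fitted mask
        bit-identical, because selection sees only training spectra."""
        pre = small_preprocessed
        train = pre.subset(range(0, pre.n_spectra, 2))
        mask_a = select_features(train.intensities, train.y, train.shifts, seed=0)
        mask_b = select_features(train.intensities.copy(), train.y, train.shifts, seed=0)
        assert np.array_equal(mask_a.selected_idx, mask_b.selected_idx)
        assert mask_a.dropped_clusters == mask_b.dropped_clusters


class TestApplyMaskAndSerialization:
    def test_full_mask_is_identity(self, small_preprocessed):
        pre = small_preprocessed
        mask = select_features(pre.intensities, pre.y, pre.shifts, n_drop=0, seed=0)
        out = apply_mask(pre, mask)
        assert np.array_equal(out.intensities, pre.intensities)

    def test_masked_shapes(self, small_preprocessed):
        pre = small_preprocessed
        mask = select_features(pre.intensities, pre.y, pre.shifts, seed=0)
        out = apply_mask(pre, mask)
        assert out.n_spectra == pre.n_spectra
        assert out.n_shifts == mask.selected_idx.size

    def test_grid_mismatch_rejected(self, small_preprocessed):
        pre = small_preprocessed
        mask = select_features(pre.intensities, pre.y, pre.shifts, seed=0)
        narrowed = pre.select_shifts(range(pre.n_shifts // 2))
        with pytest.raises(ValueError, match="grid"):
            apply_mask(narrowed, mask)

    def test_mask_json_roundtrip(self, small_preprocessed, tmp_path):
        pre = small_preprocessed
        mask = select_features(pre.intensities, pre.y, pre.shifts, seed=0)
        path = tmp_path / "mask.json"
        mask.to_json(path)
        loaded = FeatureMask.from_json(path)
        assert np.array_equal(loaded.selected_idx, mask.selected_idx)
        assert loaded.dropped_clusters == mask.dropped_clusters
        assert np.allclose(loaded.shifts, mask.shifts)


class TestKMeansShiftSelectorEstimator:
    def test_fit_transform_matches_functional_mask(self, small_preprocessed):
        pre = small_preprocessed
        sel = KMeansShiftSelector(random_state=0, shifts=pre.shifts)
        out = sel.fit_transform(pre.intensities, pre.y)
        mask = select_features(pre.intensities, pre.y, pre.shifts, seed=0)
        assert np.array_equal(sel.selected_idx_, mask.selected_idx)
        assert np.allclose(out, pre.intensities[:, mask.selected_idx])

    def test_transform_applies_training_mask_to_new_data(self, small_preprocessed):
        pre = small_preprocessed
        train = pre.subset(range(0, pre.n_spectra, 2))
        test = pre.subset(range(1, pre.n_spectra, 2))
        sel = KMeansShiftSelector(random_state=0).fit(train.intensities, train.y)
        out = sel.transform(test.intensities)
        assert out.shape == (test.n_spectra, sel.selected_idx_.size)

    def test_clone_and_get_params(self):
        sel = KMeansShiftSelector(k_max=7, n_drop=2)
        assert clone(sel).get_params()["k_max"] == 7
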