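"""Blind source separation machinery: whitening, Infomax, group ICA,
GIG-ICA, IVA-GL, and the joint separation metric."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from fmribss.decomposition import (ConvergenceError, amari_isi, gig_ica,
                                   group_ica, infomax_ica, iva_gl, joint_isi,
                                   pca_whiten, zscore_maps)
from fmribss.synthetic import SimConfig, assemble_dataset


def best_match_corrs(est_maps, true_maps):
    """Mean absolute correlation after optimal (Hungarian) matching."""
    ez = zscore_maps(np.asarray(est_maps))
    tz = zscore_maps(np.asarray(true_maps))
    corr = np.abs(ez @ tz.T / ez.shape[1])
    rows, cols = linear_sum_assignment(-corr)
    return corr[rows, cols]


class TestPcaWhiten:
    @pytest.mark.parametrize("seed", range(3))
    def test_whitening_contract(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((10, 100))
        res = pca_whiten(data, 5)
        cov = res.reduced @ res.reduced.T / 99
        assert np.abs(cov - np.eye(5)).max() < 1e-8

    def test_exact_rank_explains_everything(self, rng):
        basis = rng.standard_normal((3, 50))
        data = rng.standard_normal((8, 3)) @ basis
        res = pca_whiten(data, 3)
        assert res.explained_variance.sum() == pytest.approx(1.0, abs=1e-10)

    def test_k_beyond_rank_rejected(self, rng):
        data = rng.standard_normal((8, 3)) @ rng.standard_normal((3, 50))
        with pytest.raises(ValueError, match="rank 3"):
            pca_whiten(data, 4)

    def test_projection_backprojection_identity_on_subspace(self, rng):
        data = rng.standard_normal((6, 200))
        res = pca_whiten(data, 4)
        roundtrip = res.projection @ res.back_projection
        assert np.allclose(roundtrip, np.eye(4), atol=1e-8)


class TestInfomax:
    def test_recovers_laplacian_sources(self):
        rng = np.random.default_rng(0)
        sources = rng.laplace(size=(3, 20000))
        mixed = rng.standard_normal((3, 3)) @ sources
        white = pca_whiten(mixed, 3)
        est, _ = infomax_ica(white.reduced, seed=0)
        assert best_match_corrs(est, sources).min() >= 0.95

    def test_gaussian_sources_still_converge(self):
        rng = np.random.default_rng(0)
        mixed = rng.standard_normal((2, 2)) @ rng.standard_normal((2, 5000))
        white = pca_whiten(mixed, 2)
        est, unmix = infomax_ica(white.reduced, seed=0)  # no error raised
        assert est.shape == (2, 5000)

    def test_deterministic_given_seed(self, rng):
        white = pca_whiten(rng.laplace(size=(3, 3)) @
                           rng.laplace(size=(3, 5000)), 3)
        _, w1 = infomax_ica(white.reduced, seed=5)
        _, w2 = infomax_ica(white.reduced, seed=5)
        assert np.array_equal(w1, w2)

    def test_nonconvergence_raises_with_gradient_norm(self, rng):
        white = pca_whiten(rng.laplace(size=(3, 3)) @
                           rng.laplace(size=(3, 5000)), 3)
        with pytest.raises(ConvergenceError, match="gradient norm"):
            infomax_ica(white.reduced, seed=0, max_iter=2)

    def test_matches_external_infomax_implementation(self):
        # independent cross-check: mne's (extended) infomax on the same
        # mixture must find sources equivalent to ours up to permutation
        mne = pytest.importorskip("mne")
        from mne.preprocessing.infomax_ import infomax as mne_infomax
        rng = np.random.default_rng(1)
        sources = rng.laplace(size=(3, 10000))
        mixed = rng.standard_normal((3, 3)) @ sources
        white = pca_whiten(mixed, 3)
        ours, _ = infomax_ica(white.reduced, seed=0)
        w_mne = mne_infomax(white.reduced.T, extended=False,
                            random_state=0, max_iter=800)
        theirs = w_mne @ white.reduced
        corr = np.abs(np.corrcoef(np.vstack([ours, theirs]))[:3, 3:])
        rows, cols = linear_sum_assignment(-corr)
        assert corr[rows, cols].min() >= 0.95


class TestZscoreMaps:
    def test_small_vector(self):
        z = zscore_maps(np.array([[1.0, 2.0, 3.0]]))
        assert z.mean() == pytest.approx(0.0)
        assert z.std() == pytest.approx(1.0)

    def test_idempotent(self, rng):
        maps = zscore_maps(rng.standard_normal((2, 50)))
        assert np.allclose(zscore_maps(maps), maps, atol=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            zscore_maps(np.ones((1, 10)))


class TestGroupIca:
    def test_group_maps_recover_base_maps(self):
        cfg = SimConfig(n_hc=5, n_asd=5, k_sources=3, grid_shape=(10, 10, 10),
                        n_timepoints=120, isv_sigma=0.5, amp_sigma=0.1,
                        var_inflation_asd=1.0, noise_sigma=0.1, seed=0)
        dataset, truth = assemble_dataset(cfg)
        dec = group_ica(dataset, 3, seed=0)
        assert best_match_corrs(dec.group_maps, truth.base_maps).mean() >= 0.9

    def test_no_isv_subject_maps_equal_group_maps(self):
        cfg = SimConfig(n_hc=3, n_asd=2, k_sources=3, grid_shape=(10, 10, 10),
                        n_timepoints=120, isv_sigma=0.0, amp_sigma=0.0,
                        var_inflation_asd=1.0, noise_sigma=0.05, seed=1)
        dataset, _ = assemble_dataset(cfg)
        dec = group_ica(dataset, 3, seed=0)
        corr = np.abs(np.diag(dec.spatial_maps[0] @ dec.group_maps.T
                              / dec.group_maps.shape[1]))
        assert corr.min() >= 0.99

    def test_single_subject_degenerates_to_subject_ica(self):
        cfg = SimConfig(n_hc=1, n_asd=1, k_sources=2, grid_shape=(8, 8, 8),
                        n_timepoints=80, noise_sigma=0.1,
                        var_inflation_asd=1.0, seed=2)
        dataset, _ = assemble_dataset(cfg)
        dataset.subjects = dataset.subjects[:1]
        dec = group_ica(dataset, 2, seed=0)
        assert len(dec.spatial_maps) == 1

    def test_maps_are_zscored(self, small_dataset):
        dec = group_ica(small_dataset[0], 3, seed=0)
        for maps in dec.spatial_maps:
            assert np.allclose(maps.mean(axis=1), 0, atol=1e-9)
            assert np.allclose(maps.std(axis=1), 1, atol=1e-9)


class TestGigIca:
    def test_fixed_point_without_isv_or_noise(self):
        cfg = SimConfig(n_hc=3, n_asd=2, k_sources=3, grid_shape=(10, 10, 10),
                        n_timepoints=120, isv_sigma=0.0, amp_sigma=0.0,
                        var_inflation_asd=1.0, noise_sigma=0.0, seed=1)
        dataset, _ = assemble_dataset(cfg)
        baseline = group_ica(dataset, 3, seed=0)
        dec = gig_ica(dataset, baseline.group_maps, seed=0)
        refs = baseline.group_maps
        corr = np.abs(np.diag(dec.spatial_maps[0] @ refs.T / refs.shape[1]))
        assert corr.min() >= 0.999

    def test_beats_back_reconstruction_under_isv(self):
        # the guided estimate should track each subject's own map better
        # than least-squares back-reconstruction from group maps
        cfg = SimConfig(n_hc=8, n_asd=7, k_sources=4, grid_shape=(12, 12, 12),
                        n_timepoints=150, isv_sigma=2.0, amp_sigma=0.1,
                        var_inflation_asd=1.0, noise_sigma=0.5, seed=2)
        dataset, truth = assemble_dataset(cfg)
        baseline = group_ica(dataset, 4, seed=0)
        guided = gig_ica(dataset, baseline.group_maps, seed=0)
        n = dataset.n_subjects

        def mean_truth_corr(dec):
            return np.mean([
                best_match_corrs(dec.spatial_maps[i],
                                 truth.subject_maps[i]).mean()
                for i in range(n)])

        assert mean_truth_corr(guided) > mean_truth_corr(baseline)

    def test_pure_constraint_tracks_reference_at_least_as_well(self):
        # lambda = 0 removes the negentropy term: the reference correlation
        # can only be at least that of the balanced objective
        cfg = SimConfig(n_hc=2, n_asd=2, k_sources=3, grid_shape=(10, 10, 10),
                        n_timepoints=120, isv_sigma=1.0, amp_sigma=0.1,
                        var_inflation_asd=1.0, noise_sigma=0.3, seed=3)
        dataset, _ = assemble_dataset(cfg)
        baseline = group_ica(dataset, 3, seed=0)
        refs = baseline.group_maps

        def ref_corr(dec):
            return np.mean([np.abs(np.diag(m @ refs.T / refs.shape[1]))
                            for m in dec.spatial_maps])

        pure = gig_ica(dataset, refs, lambda_weight=0.0, seed=0)
        balanced = gig_ica(dataset, refs, lambda_weight=0.5, seed=0)
        assert ref_corr(pure) >= ref_corr(balanced) - 1e-9


class TestIvaGl:
    @pytest.mark.parametrize("seed", range(5))
    def test_joint_isi_on_correlated_sources(self, seed):
        cfg = SimConfig(n_hc=3, n_asd=2, k_sources=3, grid_shape=(10, 10, 10),
                        n_timepoints=120, isv_sigma=0.5, amp_sigma=0.1,
                        var_inflation_asd=1.0, noise_sigma=0.1, seed=seed)
        dataset, truth = assemble_dataset(cfg)
        dec = iva_gl(dataset, 3, seed=seed)
        est_mixings = [np.linalg.pinv(u) for u in dec.info["unmixings"]]
        isi = joint_isi(est_mixings, truth.subject_tcs)
        assert isi <= 0.1

    def test_single_subject_still_converges(self):
        cfg = SimConfig(n_hc=1, n_asd=1, k_sources=2, grid_shape=(8, 8, 8),
                        n_timepoints=80, noise_sigma=0.1,
                        var_inflation_asd=1.0, seed=1)
        dataset, _ = assemble_dataset(cfg)
        dataset.subjects = dataset.subjects[:1]
        dec = iva_gl(dataset, 2, seed=0)
        assert len(dec.spatial_maps) == 1

    def test_deterministic_given_seed(self, small_dataset):
        d1 = iva_gl(small_dataset[0], 3, seed=4)
        d2 = iva_gl(small_dataset[0], 3, seed=4)
        for m1, m2 in zip(d1.spatial_maps, d2.spatial_maps):
            assert np.array_equal(m1, m2)

    def test_component_order_aligned_across_subjects(self, small_dataset):
        dataset, truth = small_dataset
        dec = iva_gl(dataset, 3, seed=0)
        # component c of subject 0 should match component c (not some other)
        # of subject 1 better than any alternative on average
        a, b = dec.spatial_maps[0], dec.spatial_maps[1]
        corr = np.abs(a @ b.T / a.shape[1])
        assert np.all(np.argmax(corr, axis=1) == np.arange(3))


class TestIsi:
    def test_perfect_separation_is_zero(self, rng):
        a = rng.standard_normal((4, 4))
        assert joint_isi([a], [a]) == pytest.approx(0.0, abs=1e-10)

    def test_column_permutation_is_zero(self, rng):
        a = rng.standard_normal((4, 4))
        perm = np.eye(4)[[2, 0, 3, 1]]
        assert joint_isi([a @ perm], [a]) == pytest.approx(0.0, abs=1e-10)

    def test_all_ones_matrix_is_one(self):
        assert amari_isi(np.ones((4, 4))) == pytest.approx(1.0)

    def test_inconsistent_permutations_penalized(self, rng):
        # same permutation in every subject: fine; different ones: not
        a = rng.standard_normal((3, 3))
        p1 = np.eye(3)[[1, 2, 0]]
        p2 = np.eye(3)[[2, 0, 1]]
        same = joint_isi([a @ p1, a @ p1], [a, a])
        mixed = joint_isi([a @ p1, a @ p2], [a, a])
        assert same == pytest.approx(0.0, abs=1e-10)
        assert mixed > 0.3

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            amari_isi(np.zeros((3, 3)))
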