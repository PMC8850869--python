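"""Linked-ICA core: recovery, free energy, invariances, maps, weights."""

import numpy as np
import pytest

import bigflica as bf
from bigflica.data import ModalityData, zscore_features
from bigflica.flica import modality_similarity, modality_weight_matrix


def _assert_free_energy_monotone(model):
    fe = model.free_energy_trace
    assert np.all(np.diff(fe) >= -1e-6 * np.maximum(1.0, np.abs(fe[:-1])))


class TestFit:
    def test_recovery_on_simulation(self, tiny_fit):
        dataset, truth, model = tiny_fit
        match = bf.greedy_match(model.H_star, truth.H)
        assert match.mean_correlation > 0.85
        _assert_free_energy_monotone(model)

    def test_scale_invariance_of_one_raw_modality(self):
        rng = np.random.default_rng(12)
        Y1 = rng.standard_normal((60, 8)) @ rng.standard_normal((8, 200))
        Y2 = rng.standard_normal((60, 8)) @ rng.standard_normal((8, 200))
        z = lambda Y: zscore_features(ModalityData("m", Y)).matrix
        m1 = bf.flica_fit([z(Y1), z(Y2)], L=6, n_iter=40, seed=3)
        m2 = bf.flica_fit([z(10.0 * Y1), z(Y2)], L=6, n_iter=40, seed=3)
        np.testing.assert_allclose(m1.H_star, m2.H_star, atol=1e-8)

    def test_modality_order_invariance(self, tiny_sim):
        _, dataset, truth = tiny_sim
        m1 = bf.flica_fit([dataset[0].matrix, dataset[1].matrix], L=8, n_iter=120, seed=0)
        m2 = bf.flica_fit([dataset[1].matrix, dataset[0].matrix], L=8, n_iter=120, seed=0)
        r1 = bf.greedy_match(m1.H_star, truth.H).mean_correlation
        r2 = bf.greedy_match(m2.H_star, truth.H).mean_correlation
        assert abs(r1 - r2) < 0.05
        _assert_free_energy_monotone(m1)

    def test_single_modality_bayesian_ica(self):
        cfg = bf.SimulationConfig(
            n_subjects=250, grid=(12, 12, 12), n_shared=8,
            n_unique_per_modality=0, n_modalities=1, snr=4.0, seed=11,
        )
        ds, truth = bf.simulate_dataset(cfg)
        model = bf.flica_fit([ds[0].matrix], L=8, n_iter=250, seed=0)
        match = bf.greedy_match(model.H_star, truth.H)
        assert match.mean_correlation >= 0.9
        _assert_free_energy_monotone(model)

    def test_determinism(self, tiny_sim):
        _, dataset, _ = tiny_sim
        ins = [m.matrix for m in dataset]
        m1 = bf.flica_fit(ins, L=5, n_iter=30, seed=42)
        m2 = bf.flica_fit(ins, L=5, n_iter=30, seed=42)
        np.testing.assert_array_equal(m1.H_star, m2.H_star)
        np.testing.assert_array_equal(m1.free_energy_trace, m2.free_energy_trace)

    def test_scale_convention_unit_rms_columns(self, tiny_fit):
        _, _, model = tiny_fit
        rms = np.sqrt(np.mean(model.H_star**2, axis=0))
        np.testing.assert_allclose(rms, 1.0, rtol=0.05)
        for W in model.W:
            assert np.all(W >= 0)

    def test_l_too_large_errors(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="too large"):
            bf.flica_fit([rng.standard_normal((10, 50))], L=10)


class TestSpatialMaps:
    def test_noiseless_recovery_of_ground_truth_maps(self):
        """OLS regression of noiseless data on the true subject mode recovers X."""
        from bigflica.flica import FlicaModel
        from bigflica.simulate import simulate_spatial_map

        rng = np.random.default_rng(1)
        n, L = 80, 4
        X = np.stack(
            [simulate_spatial_map((10, 10, 10), rng).ravel(order="F") for _ in range(L)]
        )
        H = rng.standard_normal((n, L))
        Y = H @ X
        model = FlicaModel(
            H_star=H, W=[np.ones(L)], X=[X], noise_precision=[1.0],
            free_energy_trace=np.zeros(1), L=L, priors={}, seed=0,
        )
        ds = [ModalityData("m", Y)]
        smaps = bf.reconstruct_spatial_maps(model, None, ds)
        # per-map z-scoring is affine per row, so correlation with X is preserved
        match = bf.greedy_match(smaps.maps[0].T, X.T)
        assert match.mean_correlation > 0.99
        assert np.allclose(match.per_pair_abs_correlation, 1.0, atol=1e-8)

    def test_duplicated_subject_mode_column_errors(self, tiny_sim):
        _, dataset, _ = tiny_sim
        model = bf.flica_fit([m.matrix for m in dataset], L=4, n_iter=10, seed=0)
        model.H_star[:, 1] = model.H_star[:, 0]
        with pytest.raises(ValueError, match="rank"):
            bf.reconstruct_spatial_maps(model, None, dataset)

    def test_dropped_voxels_are_zero_in_reexpanded_maps(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((50, 40))
        Y[:, 7] = 3.0  # constant column, dropped at z-scoring
        ds = [zscore_features(ModalityData("m", Y, mask=np.arange(40), grid_shape=(40, 1, 1)))]
        model = bf.flica_fit([ds[0].matrix], L=3, n_iter=30, seed=0)
        smaps = bf.reconstruct_spatial_maps(model, None, ds)
        assert smaps.maps[0].shape == (3, 40)
        np.testing.assert_array_equal(smaps.maps[0][:, 7], 0.0)
        vol = smaps.to_volume(0)
        assert vol.shape == (40, 1, 1, 3)


class TestModalityWeights:
    def test_columns_sum_to_one(self, tiny_fit):
        _, _, model = tiny_fit
        Wmat = modality_weight_matrix(model)
        np.testing.assert_allclose(Wmat.sum(axis=0), 1.0, atol=1e-10)

    def test_unique_component_mass_concentrates(self, tiny_fit):
        dataset, truth, model = tiny_fit
        Wmat = modality_weight_matrix(model)
        # find the estimated components matched to modality-0-unique truth comps
        match = bf.greedy_match(model.H_star, truth.H)
        n_sh = truth.n_shared
        unique0 = {v for v in range(n_sh, n_sh + 2)}
        rows = [e for e, t in match.pairing.items() if t in unique0]
        assert rows, "no estimated component matched a unique source"
        # row-normalize to compare mass across modalities within a mode
        for r in rows:
            row = np.stack(model.W, axis=1)[r]
            assert row[0] / row.sum() > 0.8

    def test_duplicated_modalities_have_cosine_similar_columns(self):
        rng = np.random.default_rng(3)
        n, L, p = 100, 5, 400
        H = rng.standard_normal((n, L))
        X = rng.standard_normal((L, p))
        Y = H @ X + 0.3 * rng.standard_normal((n, p))
        model = bf.flica_fit([Y, Y.copy()], L=L, n_iter=100, seed=0)
        sim = modality_similarity(modality_weight_matrix(model))
        assert sim[0, 1] > 0.95


class TestModalitySimilarity:
    def test_definition_properties(self):
        rng = np.random.default_rng(4)
        W = np.abs(rng.standard_normal((10, 4)))
        S = modality_similarity(W)
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(S), 1.0)
        assert np.all(S >= 0) and np.all(S <= 1 + 1e-12)

    def test_orthogonal_patterns_zero(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [2.0, 0.0]])
        assert modality_similarity(W)[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_column_errors(self):
        with pytest.raises(ValueError, match="zero"):
            modality_similarity(np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_needs_two_modalities(self):
        with pytest.raises(ValueError, match="two"):
            modality_similarity(np.ones((5, 1)))
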