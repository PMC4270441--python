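"""Ridge encoding models, explainable variance and RDM analyses."""

import numpy as np
import pytest

from repbench.data import FeatureMatrix, TrialTensor
from repbench.encoding import (RidgeEncoder, compute_rdm,
                               explainable_ceiling, explained_explainable,
                               it_fit_representation, object_average,
                               object_stratified_splits, rdm_similarity,
                               ridge_encode, split_half_rdm_consistency)
from repbench.simulate import GeneratorConfig, make_stimulus_set


class TestRidgeEncode:
    def test_planted_linear_map_recovered(self, rng, latent, stimuli):
        B = rng.standard_normal((latent.n_features, 8))
        neural = FeatureMatrix(latent.values @ B
                               + 0.001 * rng.standard_normal((latent.n_images, 8)),
                               feature_kind="neural_multiunit")
        res = ridge_encode(latent, neural, stimuli=stimuli, n_splits=3, seed=0)
        assert res.site_r.min() > 0.99

    def test_self_prediction_is_perfect(self, latent, stimuli):
        neural = FeatureMatrix(latent.values, feature_kind="neural_multiunit")
        res = ridge_encode(latent, neural, stimuli=stimuli, n_splits=2, seed=1)
        assert res.site_r.min() > 0.999

    def test_unrelated_representations_predict_nothing(self, rng, stimuli):
        a = FeatureMatrix(rng.standard_normal((len(stimuli), 15)))
        b = FeatureMatrix(rng.standard_normal((len(stimuli), 10)),
                          feature_kind="neural_multiunit")
        res = ridge_encode(a, b, stimuli=stimuli, n_splits=3, seed=2)
        assert abs(np.median(res.site_r)) < 0.15

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="image rows"):
            ridge_encode(FeatureMatrix(rng.random((5, 2))),
                         FeatureMatrix(rng.random((6, 2))))


class TestExplainedExplainable:
    def test_closed_form_cases(self):
        assert explained_explainable(0.8, 0.8) == pytest.approx(100.0)
        assert explained_explainable(0.0, 0.9) == pytest.approx(0.0)
        assert explained_explainable(0.3, 0.6) == pytest.approx(25.0)

    def test_nonpositive_ceiling_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            out = explained_explainable(np.array([0.5, 0.5]),
                                        np.array([0.7, -0.1]))
        assert np.isnan(out[1]) and np.isfinite(out[0])

    def test_overshoot_flagged_not_clipped(self):
        with pytest.warns(UserWarning, match="exceeds"):
            out = explained_explainable(0.9, 0.5)
        assert out > 100.0

    def test_recovers_planted_shared_variance_fraction(self, rng):
        # site = shared component (fraction f of signal variance) + private
        # signal + trial noise; encoding should explain ~f of the explainable
        f, T, n_img, n_sites = 0.5, 12, 400, 8
        model_feats = rng.standard_normal((n_img, 20))
        w = rng.standard_normal((20, n_sites)) / np.sqrt(20)
        shared = model_feats @ w
        shared *= np.sqrt(f) / shared.std(axis=0)
        private = rng.standard_normal((n_img, n_sites)) * np.sqrt(1 - f)
        signal = shared + private
        counts = (signal.T[:, :, None]
                  + rng.standard_normal((n_sites, n_img, T)) * 0.7)
        tensor = TrialTensor(counts=counts)
        neural = FeatureMatrix(counts.mean(axis=2).T,
                               feature_kind="neural_multiunit")
        enc = RidgeEncoder(n_splits=3, random_state=0)
        enc.fit(FeatureMatrix(model_feats), neural, trial_tensor=tensor)
        assert 100 * f - 15 < enc.median_explained_explainable_ < 100 * f + 15


class TestObjectAverage:
    def test_default_task_has_49_objects(self, rng):
        cfg = GeneratorConfig()
        stim = make_stimulus_set(cfg)
        rep = FeatureMatrix(rng.standard_normal((len(stim), 5)))
        M, names = object_average(rep, stim)
        assert M.shape == (49, 5)
        assert len(names) == 49

    def test_single_image_per_object_is_identity(self, rng):
        cfg = GeneratorConfig(n_categories=2, n_objects_per_category=2,
                              n_images_per_object=1)
        stim = make_stimulus_set(cfg)
        rep = FeatureMatrix(rng.standard_normal((4, 3)))
        M, _ = object_average(rep, stim)
        assert np.allclose(M, rep.values)

    def test_permutation_invariant_within_object(self, rng, stimuli):
        rep = rng.standard_normal((len(stimuli), 4))
        M1, _ = object_average(rep, stimuli)
        perm = np.arange(len(stimuli))
        # swap two images of the same object
        obj = stimuli.object_ids
        same = np.where(obj == obj[0])[0][:2]
        perm[same] = perm[same[::-1]]
        M2, _ = object_average(rep[perm], stimuli)
        assert np.allclose(M1, M2)


class TestRDM:
    def test_extreme_entries(self):
        M = np.array([[1.0, 2.0, 3.0],
                      [1.0, 2.0, 3.0],      # identical -> 0
                      [3.0, 2.0, 1.0]])     # anti-correlated -> 2
        rdm = compute_rdm(M)
        assert rdm[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert rdm[0, 2] == pytest.approx(2.0)
        assert np.allclose(rdm, rdm.T)
        assert np.all(np.diag(rdm) == 0)

    def test_independent_vectors_near_one(self, rng):
        rdm = compute_rdm(rng.standard_normal((10, 1000)))
        iu = np.triu_indices(10, 1)
        assert abs(rdm[iu].mean() - 1.0) < 0.05

    def test_constant_object_vector_named_in_error(self, rng):
        M = rng.standard_normal((4, 6))
        M[2] = 3.0
        with pytest.raises(ValueError, match="2"):
            compute_rdm(M)

    def test_similarity_identity_and_rank_invariance(self, rng):
        A = compute_rdm(rng.standard_normal((12, 30)))
        assert rdm_similarity(A, A) == pytest.approx(1.0)
        assert rdm_similarity(A, np.sqrt(A)) == pytest.approx(1.0)
        B = compute_rdm(rng.standard_normal((12, 30)))
        assert abs(rdm_similarity(A, B)) < 3 / np.sqrt(len(np.triu_indices(12, 1)[0]))
        with pytest.raises(ValueError, match="shape"):
            rdm_similarity(A, np.zeros((5, 5)))

    def test_invariance_to_scaling_rotation_and_object_shifts(self, rng):
        # correlation distance centers each object vector, so the exact
        # invariance class is: global scalings, per-object additive shifts,
        # and rotations of the centered feature space (orthogonal maps that
        # fix the all-ones direction)
        d = 15
        X = rng.standard_normal((20, d))
        R, _ = np.linalg.qr(rng.standard_normal((d - 1, d - 1)))
        H, _ = np.linalg.qr(np.column_stack([np.ones(d), rng.standard_normal((d, d - 1))]))
        Q = H @ np.block([[np.ones((1, 1)), np.zeros((1, d - 1))],
                          [np.zeros((d - 1, 1)), R]]) @ H.T
        assert np.allclose(Q @ np.ones(d), np.ones(d))
        shifts = rng.standard_normal((20, 1))
        Y = 3.7 * X @ Q + shifts          # per-object additive constants
        rho = rdm_similarity(compute_rdm(X), compute_rdm(Y))
        assert rho == pytest.approx(1.0)


class TestSplitHalfRDM:
    def test_many_clean_sites_give_high_consistency(self, rng, stimuli, latent):
        # halves must hold enough sites that each random projection
        # preserves the latent Gram structure
        W = rng.standard_normal((latent.n_features, 1600))
        neural = FeatureMatrix(latent.values @ W, feature_kind="neural_multiunit")
        out = split_half_rdm_consistency(neural, stimuli, n_repeats=5,
                                         n_splits=2, seed=0)
        assert out["rho_mean"] > 0.9

    def test_pure_noise_sites_give_no_consistency(self, rng, stimuli):
        neural = FeatureMatrix(rng.standard_normal((len(stimuli), 40)),
                               feature_kind="neural_multiunit")
        out = split_half_rdm_consistency(neural, stimuli, n_repeats=5,
                                         n_splits=2, seed=1)
        assert abs(out["rho_mean"]) < 0.15

    def test_more_sites_increase_consistency(self, rng, stimuli, latent):
        def rho(n_sites, seed):
            W = np.random.default_rng(seed).standard_normal(
                (latent.n_features, n_sites))
            vals = latent.values @ W + 4.0 * np.random.default_rng(seed + 1).\
                standard_normal((latent.n_images, n_sites))
            neural = FeatureMatrix(vals, feature_kind="neural_multiunit")
            return split_half_rdm_consistency(neural, stimuli, n_repeats=4,
                                              n_splits=2, seed=2)["rho_mean"]
        assert rho(64, 5) > rho(8, 5)

    def test_requires_two_sites(self, rng, stimuli):
        neural = FeatureMatrix(rng.standard_normal((len(stimuli), 1)),
                               feature_kind="neural_multiunit")
        with pytest.raises(ValueError, match="2 sites"):
            split_half_rdm_consistency(neural, stimuli)


class TestITFit:
    def test_identical_representations_reach_ceiling(self, latent, stimuli):
        neural = FeatureMatrix(latent.values, feature_kind="neural_multiunit")
        fits = it_fit_representation(latent, neural, stimuli, n_splits=2, seed=0)
        for fit in fits:
            M, _ = object_average(neural, stimuli, fit["test_idx"])
            assert rdm_similarity(fit["rdm"], compute_rdm(M)) > 0.95

    def test_noise_model_representation_explains_nothing(self, rng, stimuli,
                                                         latent):
        noise_rep = FeatureMatrix(rng.standard_normal((len(stimuli), 15)))
        W = rng.standard_normal((latent.n_features, 20))
        neural = FeatureMatrix(latent.values @ W, feature_kind="neural_multiunit")
        fits = it_fit_representation(noise_rep, neural, stimuli, n_splits=2,
                                     seed=1)
        rhos = []
        for fit in fits:
            M, _ = object_average(neural, stimuli, fit["test_idx"])
            rhos.append(rdm_similarity(fit["rdm"], compute_rdm(M)))
        assert abs(np.mean(rhos)) < 0.2

    def test_fit_and_rdm_images_never_overlap(self, latent, stimuli):
        splits = object_stratified_splits(stimuli, n_splits=3, seed=4)
        neural = FeatureMatrix(latent.values, feature_kind="neural_multiunit")
        fits = it_fit_representation(latent, neural, stimuli, splits=splits)
        for (train, _), fit in zip(splits, fits):
            assert len(np.intersect1d(train, fit["test_idx"])) == 0
            # every object appears in every test split
            assert len(set(stimuli.object_ids[fit["test_idx"]])) == stimuli.n_objects


def test_explainable_ceiling_restricted_to_training_images(tensor):
    full = explainable_ceiling(tensor, seed=0)
    half = explainable_ceiling(tensor, image_idx=np.arange(tensor.n_images // 2),
                               seed=0)
    assert full.shape == half.shape == (tensor.n_sites,)
    assert np.all(np.isfinite(full))
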