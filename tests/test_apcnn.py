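"""Feature stack, pseudoinverse training, CRF refinement, particle filter."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import ndimage
from sklearn.base import clone

from mammo_qwtapcnn import synth_io
from mammo_qwtapcnn.apcnn import (
    APCNNClassifier,
    APCNNConfig,
    CRFParams,
    ParticleFilterConfig,
    bayes_posterior,
    build_features,
    conv_bank,
    crf_energy,
    crf_kernel_matrix,
    crf_refine,
    dilate_kernel,
    load_model,
    localize,
    mass_probability_map,
    predict_image,
    refine_mass_mask,
    save_model,
    solve_output_weights,
    _make_kernels,
)
from mammo_qwtapcnn.morphseg import MorphSegmenter


class TestFeatureStack:
    def test_zero_mean_kernels_on_constant_image_give_zero(self):
        rng = np.random.default_rng(0)
        kernels = _make_kernels(rng, 3, 1, 9)
        out = conv_bank(np.full((1, 32, 32), 0.5), kernels)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_feature_vector_deterministic(self, benign_phantom):
        cfg = APCNNConfig(seed=3)
        a = build_features(benign_phantom.image, cfg).vector
        b = build_features(benign_phantom.image, cfg).vector
        np.testing.assert_array_equal(a, b)
        assert a.shape == (7 * cfg.n_filters,)

    def test_stochastic_pooling_reproducible_with_rng(self, benign_phantom):
        cfg = APCNNConfig(seed=3)
        a = build_features(benign_phantom.image, cfg, np.random.default_rng(1)).vector
        b = build_features(benign_phantom.image, cfg, np.random.default_rng(1)).vector
        np.testing.assert_array_equal(a, b)

    def test_atrous_rate_one_equals_direct_convolution(self, rng):
        """The identity-rate pyramid branch must reproduce a plain filter."""
        maps = rng.normal(size=(2, 16, 16))
        kernels = rng.normal(size=(3, 2, 5, 5))
        ours = conv_bank(maps, kernels, rate=1)
        oracle = np.zeros_like(ours)
        for o in range(3):
            for c in range(2):
                oracle[o] += ndimage.correlate(maps[c], kernels[o, c], mode="nearest")
        np.testing.assert_array_equal(ours, oracle)

    def test_dilated_kernel_spaces_taps(self):
        k = np.arange(9, dtype=float).reshape(3, 3)
        d = dilate_kernel(k, 3)
        assert d.shape == (7, 7)
        np.testing.assert_array_equal(d[::3, ::3], k)
        assert d.sum() == k.sum()

    def test_seven_atrous_rates_enforced(self):
        with pytest.raises(ValueError):
            APCNNConfig(atrous_rates=(1, 2, 3))

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            build_features(np.zeros((32, 32), dtype=np.uint8))


class TestELMTraining:
    def test_least_squares_residual_matches_lstsq_oracle(self, rng):
        """beta attains the normal-equation optimum on random problems."""
        for _ in range(5):
            G = rng.normal(size=(50, 12))
            T = rng.normal(size=(50, 2))
            beta = solve_output_weights(G, T)
            beta_oracle, *_ = np.linalg.lstsq(G, T, rcond=None)
            r = np.linalg.norm(G @ beta - T)
            r_oracle = np.linalg.norm(G @ beta_oracle - T)
            assert abs(r - r_oracle) <= 1e-8 * max(r_oracle, 1.0)

    def test_square_invertible_interpolates_exactly(self, rng):
        G = rng.normal(size=(8, 8)) + 8 * np.eye(8)
        T = rng.normal(size=(8, 2))
        beta = solve_output_weights(G, T)
        assert np.linalg.norm(G @ beta - T) < 1e-8

    def test_duplicating_rows_leaves_solution_unchanged(self, rng):
        G = rng.normal(size=(20, 6))
        T = rng.normal(size=(20, 2))
        b1 = solve_output_weights(G, T)
        b2 = solve_output_weights(np.vstack([G, G]), np.vstack([T, T]))
        np.testing.assert_allclose(b1, b2, atol=1e-10)

    def test_degenerate_column_warns_and_solves(self, rng):
        G = rng.normal(size=(10, 4))
        G[:, 2] = 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            beta = solve_output_weights(G, rng.normal(size=(10, 2)))
        assert np.isfinite(beta).all()


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    Xb = rng.normal(2.0, 1.0, size=(40, 6))
    Xm = rng.normal(7.0, 1.0, size=(40, 6))
    X = np.vstack([Xb, Xm])
    y = np.array(["benign"] * 40 + ["malignant"] * 40)
    return X, y


class TestClassifier:

    def test_fit_predict_separable_problem(self, toy):
        X, y = toy
        clf = APCNNClassifier(seed=0).fit(X, y)
        assert (clf.predict(X) == y).mean() >= 0.95
        assert list(clf.classes_) == ["benign", "malignant"]

    def test_refit_reproduces_weights_bit_identically(self, toy):
        X, y = toy
        b1 = APCNNClassifier(seed=0).fit(X, y).output_weights_
        b2 = APCNNClassifier(seed=0).fit(X, y).output_weights_
        np.testing.assert_array_equal(b1, b2)

    def test_input_weights_frozen_by_training(self, toy):
        X, y = toy
        clf = APCNNClassifier(seed=0)
        clf.fit(X, y)
        before = [W.copy() for W, _ in clf.input_weights_]
        clf.fit(X, y)
        for W0, (W1, _) in zip(before, clf.input_weights_):
            np.testing.assert_array_equal(W0, W1)

    def test_tau_zero_never_suspicious(self, toy):
        X, y = toy
        clf = APCNNClassifier(tau=0.0, seed=0).fit(X, y)
        assert "suspicious" not in set(clf.predict_with_suspicious(X))

    def test_unreachable_tau_always_suspicious(self, toy):
        X, y = toy
        clf = APCNNClassifier(tau=1.0 + 1e-9, seed=0).fit(X, y)
        assert set(clf.predict_with_suspicious(X)) == {"suspicious"}

    def test_suspicious_rate_monotone_in_tau(self, toy):
        X, y = toy
        clf = APCNNClassifier(seed=0).fit(X, y)
        rates = [
            float(np.mean(clf.predict_with_suspicious(X, tau=t) == "suspicious"))
            for t in np.linspace(0.5, 1.0, 6)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_untrained_model_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            APCNNClassifier().predict(np.zeros((1, 4)))

    def test_sklearn_clone_compatible(self):
        clf = APCNNClassifier(tau=0.7, hidden_units=(5, 3))
        c = clone(clf)
        assert c.tau == 0.7 and c.hidden_units == (5, 3)

    def test_save_load_roundtrip(self, toy, tmp_path):
        X, y = toy
        clf = APCNNClassifier(seed=0).fit(X, y)
        save_model(tmp_path / "m.npz", clf, feature_config=APCNNConfig(seed=9))
        loaded = load_model(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.predict_proba(X), clf.predict_proba(X))
        assert loaded.feature_config_.seed == 9


def brute_force_energy(labels, unary_neglog, K):
    """Independent quadratic-loop evaluation of the CRF energy."""
    lab = np.asarray(labels).ravel()
    n = len(lab)
    e = sum(unary_neglog[i, lab[i]] for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and lab[i] != lab[j]:
                e += K[i, j]
    return float(e)


class TestCRF:
    def _toy_instance(self, rng, h=3, w=3):
        img = rng.uniform(0, 255, (h, w))
        p = rng.uniform(0.05, 0.95, (h, w, 1))
        probs = np.concatenate([p, 1 - p], axis=-1)
        return img, probs

    def test_energy_matches_brute_force_enumeration(self, rng):
        img, probs = self._toy_instance(rng)
        params = CRFParams(iterations=2)
        K = crf_kernel_matrix(img, params)
        psi = -np.log(probs.reshape(-1, 2) + 1e-12)
        for _ in range(10):
            labels = rng.integers(0, 2, 9)
            assert abs(
                crf_energy(labels, psi, K) - brute_force_energy(labels, psi, K)
            ) < 1e-3

    def test_refinement_never_above_initial_energy_small(self, rng):
        for _ in range(5):
            img, probs = self._toy_instance(rng)
            params = CRFParams(iterations=5)
            K = crf_kernel_matrix(img, params)
            psi = -np.log(probs.reshape(-1, 2) + 1e-12)
            labels, trace = crf_refine(probs, img, params)
            e_final = brute_force_energy(labels, psi, K)
            e_init = brute_force_energy(psi.argmin(axis=1), psi, K)
            assert e_final <= e_init + 1e-6

    def test_refined_energy_at_least_global_minimum(self, rng):
        img, probs = self._toy_instance(rng)
        params = CRFParams(iterations=5)
        K = crf_kernel_matrix(img, params)
        psi = -np.log(probs.reshape(-1, 2) + 1e-12)
        labels, _ = crf_refine(probs, img, params)
        best = min(
            brute_force_energy(np.array(assign), psi, K)
            for assign in itertools.product([0, 1], repeat=9)
        )
        e_final = brute_force_energy(labels, psi, K)
        assert e_final >= best - 1e-6

    def test_zero_pairwise_weights_reduce_to_argmax(self, rng):
        img, probs = self._toy_instance(rng, 4, 4)
        params = CRFParams(w1=0.0, w2=0.0)
        labels, _ = crf_refine(probs, img, params)
        np.testing.assert_array_equal(
            labels.ravel(), probs.reshape(-1, 2).argmax(axis=1)
        )

    def test_uniform_instance_energy_is_label_permutation_invariant(self):
        img = np.full((3, 3), 100.0)
        K = crf_kernel_matrix(img, CRFParams())
        psi = np.full((9, 2), -np.log(0.5))
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0])
        assert abs(crf_energy(labels, psi, K) - crf_energy(1 - labels, psi, K)) < 1e-6

    def test_unnormalized_unary_rejected(self):
        img = np.zeros((3, 3))
        probs = np.full((3, 3, 2), 0.4)
        with pytest.raises(ValueError):
            crf_refine(probs, img)

    def test_oversized_image_rejected(self):
        img = np.zeros((128, 128))
        probs = np.full((128, 128, 2), 0.5)
        with pytest.raises(ValueError, match="dense CRF"):
            crf_refine(probs, img)

    def test_refines_phantom_mass_mask(self, benign_phantom):
        from mammo_qwtapcnn.evaluation import dice
        from mammo_qwtapcnn.morphseg import extract_mass_roi, segment
        seg = segment(benign_phantom.image)
        roi = extract_mass_roi(benign_phantom.image, seg)
        refined, trace = refine_mass_mask(benign_phantom.image, seg, roi)
        assert dice(refined, benign_phantom.mask) >= 0.9
        assert trace[-1] <= trace[0] + 1e-6


class TestParticleFilter:
    def test_point_mass_likelihood_recovers_center_exactly(self):
        score = np.zeros((64, 64))
        score[40, 23] = 1.0
        cfg = ParticleFilterConfig(n_particles=50, process_std=0.0, seed=0)
        result = localize([score], cfg)
        assert result.estimate == pytest.approx((40.0, 23.0), abs=1e-9)

    def test_weights_normalized_each_step(self):
        rng = np.random.default_rng(0)
        maps = [rng.uniform(size=(32, 32)) for _ in range(4)]
        result = localize(maps, ParticleFilterConfig(seed=1))
        assert abs(result.weights.sum() - 1.0) < 1e-12
        assert (result.weights >= 0).all()

    def test_all_zero_map_falls_back_to_uniform(self):
        result = localize([np.zeros((16, 16))], ParticleFilterConfig(n_particles=40, seed=2))
        np.testing.assert_allclose(result.weights, 1.0 / 40)

    def test_static_gaussian_blob_tracked_within_three_pixels(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = np.exp(-((yy - 30) ** 2 + (xx - 41) ** 2) / 18.0)
        cfg = ParticleFilterConfig(n_particles=200, seed=3)
        est = localize([blob] * 10, cfg).estimate
        assert np.hypot(est[0] - 30, est[1] - 41) < 3.0

    def test_deterministic_given_seed(self):
        yy, xx = np.mgrid[0:32, 0:32]
        blob = np.exp(-((yy - 10) ** 2 + (xx - 20) ** 2) / 8.0)
        a = localize([blob] * 3, ParticleFilterConfig(seed=7)).estimate
        b = localize([blob] * 3, ParticleFilterConfig(seed=7)).estimate
        assert a == b

    def test_too_few_particles_rejected(self):
        with pytest.raises(ValueError):
            ParticleFilterConfig(n_particles=5)


class TestBayes:
    def test_cancellation_identity(self):
        assert bayes_posterior(0.5, 0.3, 0.5) == pytest.approx(0.3)

    def test_arithmetic_identity(self):
        assert bayes_posterior(0.9, 0.5, 0.45) == pytest.approx(1.0)

    def test_two_hypothesis_posteriors_sum_to_one(self):
        lik = (0.8, 0.3)
        prior = (0.6, 0.4)
        evidence = lik[0] * prior[0] + lik[1] * prior[1]
        total = sum(bayes_posterior(l, p, evidence) for l, p in zip(lik, prior))
        assert total == pytest.approx(1.0)

    def test_zero_evidence_rejected(self):
        with pytest.raises(ValueError):
            bayes_posterior(0.5, 0.5, 0.0)


class TestPredictImage:
    def test_full_decision_on_phantom(self, benign_phantom, malignant_phantom):
        cfg = APCNNConfig(seed=0)
        X, y = [], []
        for s in range(10):
            for label in ("benign", "malignant"):
                ph = synth_io.generate_phantom(label=label, seed=100 + s)
                vec = np.concatenate([build_features(ph.image, cfg).vector, ph.attributes])
                X.append(vec)
                y.append(label)
        clf = APCNNClassifier(seed=0).fit(np.vstack(X), np.array(y))
        decision = predict_image(
            clf, malignant_phantom.image, attributes=malignant_phantom.attributes,
            config=cfg,
        )
        assert decision.label in ("benign", "malignant", "suspicious")
        assert decision.center_estimate is not None
        true = (malignant_phantom.record.center_y, malignant_phantom.record.center_x)
        err = np.hypot(decision.center_estimate[0] - true[0],
                       decision.center_estimate[1] - true[1])
        assert err < 5.0
        assert set(decision.scores) == {"benign", "malignant"}
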