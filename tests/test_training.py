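import numpy as np
import pytest
from scipy.stats import chisquare

from anmf.activations import sigmoid
from anmf.encoder import CorruptionSpec, encoder_loss_and_grads
from anmf.model import init_model, predict_matrix
from anmf.predictor import prediction_loss
from anmf.synth import SyntheticSpec, generate
from anmf.training import (HyperParams, fit, fit_gmf_baseline, joint_loss,
                           joint_loss_and_grads, make_validation_split,
                           sample_negatives)

from conftest import make_dataset


def small_hp(**kw):
    defaults = dict(k=2, epochs=3, batch_size=4, n_neg=2, seed=0,
                    noise=CorruptionSpec("none", 0.0))
    defaults.update(kw)
    return HyperParams(**defaults)


class TestSampleNegatives:
    def test_zero_requested_gives_empty(self):
        assert sample_negatives(np.eye(3), 0).shape == (0, 2)

    def test_exhaustion_returns_all_unobserved(self):
        R = np.array([[1.0, 0.0], [0.0, 0.0]])
        neg = sample_negatives(R, 3, rng=0)
        assert {tuple(p) for p in neg} == {(0, 1), (1, 0), (1, 1)}
        with pytest.warns(UserWarning, match="unobserved"):
            neg = sample_negatives(R, 4, rng=0)
        assert {tuple(p) for p in neg} == {(0, 1), (1, 0), (1, 1)}

    def test_no_collision_with_positives(self, rng):
        R = (rng.random((12, 9)) < 0.2).astype(float)
        for seed in range(20):
            neg = sample_negatives(R, 5, rng=seed)
            assert not R[neg[:, 0], neg[:, 1]].any()
            # without replacement within one draw
            assert len({tuple(p) for p in neg}) == len(neg)

    def test_draws_uniform_over_unobserved_cells(self):
        # chi-square of per-cell inclusion counts over many seeded draws
        R = np.zeros((10, 10))
        R[np.arange(5), np.arange(5)] = 1.0  # 5 positives, 95 free cells
        counts = np.zeros(100)
        n_draws = 1000
        for seed in range(n_draws):
            neg = sample_negatives(R, 10, rng=seed)
            assert len(neg) == 50
            counts[neg[:, 0] * 10 + neg[:, 1]] += 1
        free = counts[R.ravel() == 0]
        assert counts[R.ravel() == 1].sum() == 0
        _, p = chisquare(free)
        assert p > 1e-3


class TestJointLoss:
    def test_reduces_to_prediction_loss_when_weights_zero(self, toy_dataset):
        hp = small_hp(phi=0.0, psi=0.0)
        model = init_model(np.random.default_rng(0), 4, 4, hp.k)
        pairs = np.array([[0, 0], [1, 2], [3, 3]])
        targets = np.array([1.0, 0.0, 1.0])
        total, comps = joint_loss(model, toy_dataset, pairs, targets, hp)
        scores = predict_matrix(model, toy_dataset)
        expected = sum(prediction_loss(scores[i, j], t)
                       for (i, j), t in zip(pairs, targets))
        assert total == pytest.approx(expected, rel=1e-10)
        assert comps["pred"] == pytest.approx(expected, rel=1e-10)

    def test_matches_scalar_recomputation_oracle(self, rng, toy_dataset):
        """Independent per-pair recomputation from the primitive operations."""
        hp = small_hp(alpha=0.6, beta=0.4, lam=0.01, delta=0.02, phi=0.5, psi=0.7)
        model = init_model(rng, 4, 4, hp.k)
        pairs = np.array([[0, 1], [2, 3], [0, 1], [1, 0]])  # includes a duplicate
        targets = np.array([1.0, 0.0, 1.0, 0.0])
        total, _ = joint_loss(model, toy_dataset, pairs, targets, hp)

        expected = 0.0
        R, DS, ZS = toy_dataset.R, toy_dataset.drug_sim, toy_dataset.disease_sim
        for (i, j), t in zip(pairs, targets):
            ld, _ = encoder_loss_and_grads(model.drug_encoder, R[i], DS[i],
                                           R[i], DS[i], hp.alpha, hp.lam)
            lz, _ = encoder_loss_and_grads(model.disease_encoder, R[:, j], ZS[j],
                                           R[:, j], ZS[j], hp.beta, hp.delta)
            score = predict_matrix(model, toy_dataset)[i, j]
            expected += prediction_loss(score, t) + hp.phi * ld + hp.psi * lz
        assert total == pytest.approx(expected, rel=1e-10)

    def test_empty_batch_rejected(self, toy_dataset, rng):
        model = init_model(rng, 4, 4, 2)
        with pytest.raises(ValueError):
            joint_loss(model, toy_dataset, np.empty((0, 2), int), np.empty(0), small_hp())


class TestJointGradients:
    @pytest.mark.parametrize("use_similarity", [True, False])
    def test_full_gradient_matches_central_differences(self, rng, toy_dataset,
                                                       use_similarity):
        hp = small_hp(alpha=0.6, beta=0.4, lam=0.01, delta=0.02)
        model = init_model(rng, 4, 4, hp.k, g="tanh", use_similarity=use_similarity)
        pairs = np.array([[0, 0], [1, 2], [2, 1], [0, 0]])
        targets = np.array([1.0, 0.0, 0.0, 1.0])
        _, _, grads = joint_loss_and_grads(model, toy_dataset, pairs, targets, hp)
        step = 1e-5
        for name, tensor in model.tensors().items():
            if not use_similarity and ("V1" in name or "V2" in name or "b_dec_sim" in name):
                assert not grads[name].any()
                continue
            it = np.nditer(tensor, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = tensor[idx]
                tensor[idx] = orig + step
                lp, _ = joint_loss(model, toy_dataset, pairs, targets, hp)
                tensor[idx] = orig - step
                lm, _ = joint_loss(model, toy_dataset, pairs, targets, hp)
                tensor[idx] = orig
                fd = (lp - lm) / (2 * step)
                denom = max(abs(fd), abs(grads[name][idx]), 1e-8)
                assert abs(fd - grads[name][idx]) / denom <= 1e-4, (name, idx)


class TestValidationSplit:
    def test_multi_positive_drug_contributes_exactly_one(self):
        pos = np.array([[0, 0], [0, 1], [0, 2], [1, 3]])
        split = make_validation_split(pos, (2, 4), seed=1)
        held = {tuple(p) for p in split.test_positives}
        assert len(held) == 1 and all(p[0] == 0 for p in held)
        assert len(split.train_positives) == 3
        assert (1, 3) in {tuple(p) for p in split.train_positives}

    def test_all_single_positive_drugs_warn_empty(self):
        pos = np.array([[0, 0], [1, 1]])
        with pytest.warns(UserWarning, match="single positive"):
            split = make_validation_split(pos, (2, 2), seed=0)
        assert len(split.test_positives) == 0

    def test_reproducible_given_seed(self):
        pos = np.array([[0, 0], [0, 1], [1, 0], [1, 2], [2, 1], [2, 2]])
        a = make_validation_split(pos, (3, 3), seed=5)
        b = make_validation_split(pos, (3, 3), seed=5)
        np.testing.assert_array_equal(a.test_positives, b.test_positives)


class TestFit:
    def test_zero_learning_rate_is_noop(self, toy_dataset):
        hp = small_hp(lr=0.0)
        model, _ = fit(toy_dataset, hp, validation=None)
        reinit = init_model(np.random.default_rng(
            np.random.SeedSequence(hp.seed).spawn(5)[0].entropy), 4, 4, hp.k)
        # compare against a fresh fit instead of reconstructing the init rng
        model2, _ = fit(toy_dataset, hp, validation=None)
        for a, b in zip(model.tensors().values(), model2.tensors().values()):
            np.testing.assert_array_equal(a, b)

    def test_identical_seeds_identical_parameters(self, toy_dataset):
        hp = small_hp(lr=0.1, epochs=4)
        m1, _ = fit(toy_dataset, hp, validation=None)
        m2, _ = fit(toy_dataset, hp, validation=None)
        for a, b in zip(m1.tensors().values(), m2.tensors().values()):
            np.testing.assert_array_equal(a, b)

    def test_loss_decreases_on_planted_data(self):
        ds, _ = generate(SyntheticSpec(m=30, n=20, k_true=3, density=0.1, seed=5))
        hp = HyperParams(k=8, epochs=40, batch_size=16, seed=2,
                         noise=CorruptionSpec("masking", 0.3))
        model, report = fit(ds, hp, validation=None)
        assert report.total_loss[-1] < report.total_loss[0]

    def test_lr_zero_parameters_match_across_noise_draws(self, toy_dataset):
        # with lr=0 the parameters never move even with corruption on
        hp = small_hp(lr=0.0, noise=CorruptionSpec("masking", 0.5))
        m1, _ = fit(toy_dataset, hp, validation=None)
        hp2 = small_hp(lr=0.0, noise=CorruptionSpec("none", 0.0))
        m2, _ = fit(toy_dataset, hp2, validation=None)
        for a, b in zip(m1.tensors().values(), m2.tensors().values()):
            np.testing.assert_array_equal(a, b)


class TestStaticNegatives:
    def test_static_mode_reuses_one_draw(self, toy_dataset):
        hp = small_hp(lr=0.05, epochs=4, n_neg=1, resample_negatives=False)
        m1, _ = fit(toy_dataset, hp, validation=None)
        m2, _ = fit(toy_dataset, hp, validation=None)
        for a, b in zip(m1.tensors().values(), m2.tensors().values()):
            np.testing.assert_array_equal(a, b)
        # dynamic sampling with the same seed walks a different path
        m3, _ = fit(toy_dataset, small_hp(lr=0.05, epochs=4, n_neg=1),
                    validation=None)
        assert any(not np.array_equal(a, b) for a, b in
                   zip(m1.tensors().values(), m3.tensors().values()))


class TestGmfBaseline:
    def test_prediction_component_equal_at_equal_parameters(self, rng, toy_dataset):
        """With identical weights the ANMF and GMF prediction losses coincide."""
        hp = small_hp()
        anmf = init_model(rng, 4, 4, hp.k, use_similarity=True)
        gmf = init_model(np.random.default_rng(1), 4, 4, hp.k, use_similarity=False)
        # share every tensor; GMF keeps V weights at zero
        for name, t in anmf.tensors().items():
            if "V1" in name or "V2" in name:
                t[:] = 0.0
            gmf.tensors()[name][:] = t
        pairs = np.array([[0, 1], [2, 3]])
        targets = np.array([1.0, 0.0])
        _, ca = joint_loss(anmf, toy_dataset, pairs, targets, hp)
        _, cg = joint_loss(gmf, toy_dataset, pairs, targets, hp)
        assert ca["pred"] == pytest.approx(cg["pred"], rel=1e-12)

    def test_gmf_fit_runs_and_is_deterministic(self, toy_dataset):
        hp = small_hp(lr=0.1, epochs=3)
        m1, _ = fit_gmf_baseline(toy_dataset, hp, validation=None)
        m2, _ = fit_gmf_baseline(toy_dataset, hp, validation=None)
        assert not m1.use_similarity
        assert not m1.drug_encoder.V1.any()  # similarity pathway stays off
        for a, b in zip(m1.tensors().values(), m2.tensors().values()):
            np.testing.assert_array_equal(a, b)


def test_predict_matrix_matches_per_pair_calls(rng, toy_dataset):
    from anmf.encoder import encode
    from anmf.predictor import PredictorParams, predict

    model = init_model(rng, 4, 4, 3)
    scores = predict_matrix(model, toy_dataset)
    assert scores.shape == (4, 4)
    np.testing.assert_array_equal(scores, predict_matrix(model, toy_dataset))
    for i in range(4):
        for j in range(4):
            zd = encode(model.drug_encoder, toy_dataset.R[i], toy_dataset.drug_sim[i])
            zz = encode(model.disease_encoder, toy_dataset.R[:, j],
                        toy_dataset.disease_sim[j])
            assert scores[i, j] == pytest.approx(
                predict(model.predictor, zd, zz), abs=1e-12)
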