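"""Twin network: correlation matrix, loss, training loop, inference."""

import numpy as np
import pytest

from dtitwins.barlow import (BTConfig, BTModel, DegenerateBatchError,
                             _bt_loss_and_grads, _forward_backward, bt_loss,
                             build_model, cross_correlation, train,
                             validation_loss)
from dtitwins.featurize import FeatureBundle
from dtitwins.nn import AdamW


def brute_force_correlation(zA, zB):
    """Independent double-loop evaluation of the normalised formula."""
    D = zA.shape[1]
    C = np.empty((D, D))
    for i in range(D):
        for j in range(D):
            num = sum(zA[b, i] * zB[b, j] for b in range(zA.shape[0]))
            den = np.sqrt(sum(zA[b, i] ** 2 for b in range(zA.shape[0]))) \
                * np.sqrt(sum(zB[b, j] ** 2 for b in range(zB.shape[0])))
            C[i, j] = num / den
    return C


class TestCrossCorrelation:
    def test_self_correlation_of_column_is_one(self):
        z = np.array([[1.0], [-1.0]])
        assert np.allclose(cross_correlation(z, z), [[1.0]])

    def test_sign_flip_gives_minus_one_diagonal(self):
        rng = np.random.default_rng(0)
        zA = rng.normal(size=(6, 4))
        C = cross_correlation(zA, -zA)
        assert np.allclose(np.diagonal(C), -1.0)

    def test_hand_evaluated_two_by_two(self):
        zA = np.array([[1.0, 0.0], [0.0, 1.0]])
        zB = np.array([[1.0, 1.0], [1.0, -1.0]])
        expected = np.array([[1, 1], [1, -1]]) / np.sqrt(2)
        assert np.allclose(cross_correlation(zA, zB), expected)

    def test_matches_brute_force_on_random_batches(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            zA = rng.normal(size=(8, 4))
            zB = rng.normal(size=(8, 4))
            C = cross_correlation(zA, zB)
            assert np.max(np.abs(C - brute_force_correlation(zA, zB))) <= 1e-10
            assert np.all(np.abs(C) <= 1.0 + 1e-12)

    def test_zero_column_raises_without_guard(self):
        zA = np.zeros((4, 2))
        zA[:, 1] = 1.0
        with pytest.raises(DegenerateBatchError):
            cross_correlation(zA, zA)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            cross_correlation(np.ones((4, 2)), np.ones((4, 3)))


class TestBTLoss:
    @pytest.mark.parametrize("dim", [1, 8, 512])
    @pytest.mark.parametrize("lam", [0.005, 0.1])
    def test_identity_gives_zero(self, dim, lam):
        assert bt_loss(np.eye(dim), lam) == 0.0

    def test_zero_matrix(self):
        assert bt_loss(np.zeros((2, 2)), 0.123) == 2.0

    def test_off_diagonal_weighting(self):
        C = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.isclose(bt_loss(C, 0.005), 0.0025)

    def test_non_negative_and_zero_iff_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            C = np.clip(rng.normal(size=(5, 5)), -1, 1)
            value = bt_loss(C, 0.01)
            assert value >= 0.0
            if not np.allclose(C, np.eye(5)):
                assert value > 0.0


class TestBuildModel:
    def test_output_dimensions(self, tiny_bt_config):
        model = build_model(24, 30, tiny_bt_config)
        x = np.random.default_rng(0).normal(size=(5, 24))
        em, _ = model.mol_encoder.forward(x, training=False)
        assert em.shape == (5, tiny_bt_config.embedding_dim)

    def test_seeded_init_is_bitwise_identical(self, tiny_bt_config):
        m1 = build_model(12, 10, tiny_bt_config)
        m2 = build_model(12, 10, tiny_bt_config)
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1, p2)

    def test_invalid_dims(self, tiny_bt_config):
        with pytest.raises(ValueError):
            build_model(0, 5, tiny_bt_config)


class TestGradients:
    def test_analytic_matches_numerical(self, tiny_model):
        rng = np.random.default_rng(3)
        mol = rng.normal(size=(6, 12))
        prot = rng.normal(size=(6, 10))
        _, grads = _forward_backward(tiny_model, mol, prot)
        params = tiny_model.params
        rng_idx = np.random.default_rng(4)
        for pi in range(len(params)):
            p = params[pi]
            flat = rng_idx.integers(0, p.size, size=min(3, p.size))
            for fi in flat:
                idx = np.unravel_index(fi, p.shape)
                eps, orig = 1e-6, p[idx]
                p[idx] = orig + eps
                lp, _ = _forward_backward(tiny_model, mol, prot)
                p[idx] = orig - eps
                lm, _ = _forward_backward(tiny_model, mol, prot)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[pi][idx]) <= 1e-5 * max(1.0, abs(num))

    def test_loss_grad_consistent_with_bt_loss(self):
        rng = np.random.default_rng(5)
        zA, zB = rng.normal(size=(8, 4)), rng.normal(size=(8, 4))
        loss, _, _ = _bt_loss_and_grads(zA, zB, 0.005, 0.0)
        assert np.isclose(loss, bt_loss(cross_correlation(zA, zB), 0.005))

    def test_single_step_reduces_loss(self, tiny_model):
        rng = np.random.default_rng(6)
        mol = rng.normal(size=(8, 12))
        prot = rng.normal(size=(8, 10))
        loss0, grads = _forward_backward(tiny_model, mol, prot)
        AdamW(tiny_model.params, lr=1e-3).step(grads)
        loss1, _ = _forward_backward(tiny_model, mol, prot)
        assert loss1 < loss0


class TestTraining:
    def test_deterministic_runs(self, tiny_bt_config, random_bundle):
        m1 = train(build_model(12, 10, tiny_bt_config), random_bundle)
        m2 = train(build_model(12, 10, tiny_bt_config), random_bundle)
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1, p2)
        assert m1.history == m2.history

    def test_validation_loss_improves_on_correlated_features(
            self, tiny_bt_config, random_bundle):
        model = build_model(12, 10, tiny_bt_config)
        initial = validation_loss(model, random_bundle)
        model = train(model, random_bundle)
        assert min(model.history["valid_loss"]) < initial

    def test_patience_zero_stops_at_first_non_improvement(self, random_bundle):
        cfg = BTConfig(enc_n_neurons=8, enc_n_layers=1, proj_n_neurons=4,
                       proj_n_layers=1, embedding_dim=3, batch_size=8,
                       epochs=50, patience=0, learning_rate=10.0, seed=1)
        model = train(build_model(12, 10, cfg), random_bundle)
        losses = model.history["valid_loss"]
        assert len(losses) < 50
        assert losses[-1] >= min(losses[:-1])

    def test_history_has_both_curves(self, tiny_bt_config, random_bundle):
        model = train(build_model(12, 10, tiny_bt_config), random_bundle)
        assert len(model.history["train_loss"]) == \
            len(model.history["valid_loss"]) > 0

    def test_too_few_records(self, tiny_bt_config):
        bundle = FeatureBundle(np.ones((3, 12)), np.ones((3, 10)),
                               ["a", "b", "c"])
        with pytest.raises(ValueError):
            train(build_model(12, 10, tiny_bt_config), bundle)


class TestEncode:
    def test_concatenation_order_and_length(self, tiny_model):
        rng = np.random.default_rng(7)
        bundle = FeatureBundle(rng.normal(size=(3, 12)),
                               rng.normal(size=(3, 10)),
                               ["a", "b", "c"])
        emb = tiny_model.encode(bundle)
        assert emb.shape == (3, 2 * tiny_model.config.embedding_dim)
        em, _ = tiny_model.mol_encoder.forward(bundle.molecule, training=False)
        assert np.array_equal(emb[:, :4], em)

    def test_shared_protein_shares_second_half(self, tiny_model):
        rng = np.random.default_rng(8)
        prot = rng.normal(size=(1, 10))
        bundle = FeatureBundle(rng.normal(size=(2, 12)),
                               np.vstack([prot, prot]), ["a", "b"])
        emb = tiny_model.encode(bundle)
        assert np.array_equal(emb[0, 4:], emb[1, 4:])
        assert not np.array_equal(emb[0, :4], emb[1, :4])

    def test_inference_is_deterministic(self, tiny_model):
        rng = np.random.default_rng(9)
        bundle = FeatureBundle(rng.normal(size=(4, 12)),
                               rng.normal(size=(4, 10)),
                               list("abcd"))
        assert np.array_equal(tiny_model.encode(bundle),
                              tiny_model.encode(bundle))

    def test_dimension_mismatch(self, tiny_model):
        bundle = FeatureBundle(np.ones((2, 5)), np.ones((2, 10)), ["a", "b"])
        with pytest.raises(ValueError):
            tiny_model.encode(bundle)


class TestPersistence:
    def test_round_trip_bit_identical_inference(self, tiny_bt_config,
                                                random_bundle, tmp_path):
        model = train(build_model(12, 10, tiny_bt_config), random_bundle)
        model.save(tmp_path / "model")
        back = BTModel.load(tmp_path / "model")
        assert np.array_equal(model.encode(random_bundle),
                              back.encode(random_bundle))
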