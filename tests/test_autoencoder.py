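import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pphpredict.autoencoder import (
    SAEClassifier,
    SAEConfig,
    SAELayerParams,
    SAEModel,
    decode,
    encode,
    finetune,
    finetune_cost,
    finetune_grad,
    kl_sparsity,
    predict,
    pretrain_layer,
    sparse_ae_grad,
    sparse_ae_loss,
    stack_and_attach_head,
)
from pphpredict.data import Dataset


def toy_layer(n_in=4, n_hidden=3, seed=0, scale=0.5):
    g = np.random.default_rng(seed)
    return SAELayerParams(
        g.normal(size=(n_hidden, n_in)) * scale,
        g.normal(size=n_hidden) * 0.1,
        g.normal(size=(n_in, n_hidden)) * scale,
        g.normal(size=n_in) * 0.1,
    )


class TestEncodeDecode:
    def test_zero_parameters_give_half(self):
        layer = SAELayerParams(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4))
        X = np.random.default_rng(0).uniform(size=(5, 4))
        np.testing.assert_allclose(encode(layer, X), 0.5)
        np.testing.assert_allclose(decode(layer, np.full((5, 3), 0.5)), 0.5)

    def test_large_bias_saturates(self):
        layer = SAELayerParams(np.zeros((2, 2)), np.full(2, 30.0), np.zeros((2, 2)), np.zeros(2))
        np.testing.assert_allclose(encode(layer, np.zeros((1, 2))), 1.0, atol=1e-12)

    def test_outputs_inside_unit_interval(self, rng):
        layer = toy_layer()
        X = rng.normal(size=(10, 4)) * 5
        H = encode(layer, X)
        Xh = decode(layer, H)
        assert np.all((H > 0) & (H < 1)) and np.all((Xh > 0) & (Xh < 1))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            encode(toy_layer(), np.zeros((2, 5)))
        with pytest.raises(ValueError):
            decode(toy_layer(), np.zeros((2, 5)))


class TestKlSparsity:
    def test_identity_at_target(self):
        assert kl_sparsity(np.full(4, 0.2), 0.2) == pytest.approx(0.0)

    def test_worked_value(self):
        # rho=0.05, single unit rho_hat=0.5:
        # 0.05*ln(0.1) + 0.95*ln(1.9) = 0.49462
        assert kl_sparsity(np.array([0.5]), 0.05) == pytest.approx(0.494632, abs=1e-5)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            kl_sparsity(np.array([0.0]), 0.1)
        with pytest.raises(ValueError):
            kl_sparsity(np.array([1.0]), 0.1)

    @settings(max_examples=50, derandomize=True)
    @given(rho_hat=st.floats(1e-4, 1 - 1e-4), rho=st.floats(1e-3, 1 - 1e-3))
    def test_non_negative(self, rho_hat, rho):
        v = kl_sparsity(np.array([rho_hat]), rho)
        assert v >= -1e-12
        if abs(rho_hat - rho) > 1e-9:
            assert v > 0


class TestSparseAeLoss:
    def test_reduces_to_reconstruction_error(self, rng):
        layer = toy_layer()
        X = rng.uniform(0.1, 0.9, size=(6, 4))
        cfg = SAEConfig(hidden_sizes=(3,), weight_decay=0.0, sparsity_weight=0.0)
        H = encode(layer, X)
        expected = 0.5 * np.mean(np.sum((decode(layer, H) - X) ** 2, axis=1))
        assert sparse_ae_loss(layer, X, cfg) == pytest.approx(expected)

    def test_all_terms_vanish(self):
        layer = SAELayerParams(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4))
        X = np.full((5, 4), 0.5)
        cfg = SAEConfig(hidden_sizes=(3,), weight_decay=0.1,
                        sparsity_weight=1.0, sparsity_target=0.5)
        assert sparse_ae_loss(layer, X, cfg) == pytest.approx(0.0)

    def test_sparsity_penalty_only_adds(self, rng):
        layer = toy_layer()
        X = rng.uniform(0.1, 0.9, size=(6, 4))
        base = SAEConfig(hidden_sizes=(3,), sparsity_weight=0.0)
        with_kl = SAEConfig(hidden_sizes=(3,), sparsity_weight=1.0, sparsity_target=0.05)
        assert sparse_ae_loss(layer, X, with_kl) >= sparse_ae_loss(layer, X, base)

    def test_analytic_gradient_matches_finite_differences(self, rng, numerical_gradient):
        layer = toy_layer()
        X = rng.uniform(0.1, 0.9, size=(4, 4))
        cfg = SAEConfig(hidden_sizes=(3,), weight_decay=0.01,
                        sparsity_weight=0.7, sparsity_target=0.1)
        g = sparse_ae_grad(layer, X, cfg)
        arrays = [layer.enc_weights, layer.enc_bias, layer.dec_weights, layer.dec_bias]
        for arr, analytic in zip(arrays, g):
            num = numerical_gradient(lambda: sparse_ae_loss(layer, X, cfg), arr)
            rel = np.linalg.norm(num - analytic) / (
                np.linalg.norm(num) + np.linalg.norm(analytic) + 1e-12
            )
            assert rel < 1e-5


class TestPretraining:
    def test_loss_decreases(self, rng):
        X = rng.uniform(0.1, 0.9, size=(60, 5))
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=20, seed=0)
        _, losses = pretrain_layer(X, 4, cfg, np.random.default_rng(0))
        assert losses[-1] < losses[0]

    def test_zero_learning_rate_is_noop(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 5))
        cfg = SAEConfig(hidden_sizes=(4,), learning_rate=0.0, pretrain_epochs=5, seed=0)
        layer, losses = pretrain_layer(X, 4, cfg, np.random.default_rng(0))
        assert np.allclose(losses, losses[0])

    def test_redundant_input_compresses(self):
        g = np.random.default_rng(5)
        col = g.uniform(0.2, 0.8, size=(200, 1))
        X = np.hstack([col, col, col, col])  # rank-1: compressible through 2 units
        cfg = SAEConfig(hidden_sizes=(2,), pretrain_epochs=150, learning_rate=0.8,
                        sparsity_weight=0.0, weight_decay=0.0, seed=0)
        layer, losses = pretrain_layer(X, 2, cfg, np.random.default_rng(0))
        recon_mse = 2 * losses[-1] / X.shape[1]
        assert recon_mse < X.var(axis=0).mean()

    def test_full_batch_non_increasing_with_small_step(self):
        g = np.random.default_rng(1)
        X = g.uniform(0.2, 0.8, size=(30, 4))
        cfg = SAEConfig(hidden_sizes=(3,), learning_rate=0.01, pretrain_epochs=30,
                        full_batch_rho=True, seed=0)
        _, losses = pretrain_layer(X, 3, cfg, np.random.default_rng(0))
        assert np.all(np.diff(losses) <= 1e-10)


class TestStackAndFinetune:
    def test_chained_widths(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(6, 4), pretrain_epochs=2, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        assert model.layers[0].n_hidden == 6
        assert model.layers[1].n_input == 6 and model.layers[1].n_hidden == 4
        assert model.softmax_weights.shape == (2, 4)

    def test_uniform_cost_is_ln2(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=1, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)  # zero softmax head
        cost = finetune_cost(model, two_cluster_dataset.features, two_cluster_dataset.labels)
        assert cost == pytest.approx(np.log(2))

    def test_label_out_of_range_raises(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=1, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        with pytest.raises(ValueError):
            finetune_cost(model, two_cluster_dataset.features, np.full(80, 2))

    def test_finetune_gradient_matches_finite_differences(self, rng, numerical_gradient):
        layer = toy_layer()
        layer2 = toy_layer(n_in=3, n_hidden=2, seed=1)
        model = SAEModel([layer, layer2], rng.normal(size=(2, 2)) * 0.3,
                         rng.normal(size=2) * 0.1, 2)
        X = rng.uniform(0.1, 0.9, size=(5, 4))
        y = np.array([0, 1, 1, 0, 1])
        g = finetune_grad(model, X, y, scaled=True)
        cost = lambda: finetune_cost(model, X, y, scaled=True)
        pairs = [
            (model.softmax_weights, g["softmax_weights"]),
            (model.softmax_bias, g["softmax_bias"]),
            (model.layers[0].enc_weights, g["layers"][0]["enc_weights"]),
            (model.layers[0].enc_bias, g["layers"][0]["enc_bias"]),
            (model.layers[1].enc_weights, g["layers"][1]["enc_weights"]),
            (model.layers[1].enc_bias, g["layers"][1]["enc_bias"]),
        ]
        for arr, analytic in pairs:
            num = numerical_gradient(cost, arr)
            rel = np.linalg.norm(num - analytic) / (
                np.linalg.norm(num) + np.linalg.norm(analytic) + 1e-12
            )
            assert rel < 1e-5

    def test_finetune_zero_epochs_is_identity(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=2, finetune_epochs=0, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        tuned, costs = finetune(model, two_cluster_dataset, cfg, np.random.default_rng(0))
        assert costs.shape == (1,)
        np.testing.assert_array_equal(tuned.softmax_weights, model.softmax_weights)
        np.testing.assert_array_equal(tuned.layers[0].enc_weights, model.layers[0].enc_weights)

    def test_finetune_cost_decreases(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=5, finetune_epochs=20, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        _, costs = finetune(model, two_cluster_dataset, cfg, np.random.default_rng(0))
        assert costs[-1] < costs[0]

    def test_separable_toy_reaches_full_accuracy(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=10, finetune_epochs=60, seed=0)
        clf = SAEClassifier(cfg).fit(two_cluster_dataset)
        assert clf.score(two_cluster_dataset) == 1.0

    def test_pretraining_beats_untrained_stack(self):
        """On well-separated cluster data a pretrained two-layer stack
        reaches a lower fine-tune cost than an untrained-stack control at
        equal (short) fine-tune budgets — the regime where unsupervised
        initialization matters most."""
        g = np.random.default_rng(7)
        n = 60
        X = np.vstack([g.normal(0, 0.5, size=(n, 6)), g.normal(4, 0.5, size=(n, 6))])
        ds = Dataset(X, np.repeat([0, 1], n), tuple(f"f{i}" for i in range(6)))
        cfg = SAEConfig(hidden_sizes=(5, 3), pretrain_epochs=30, finetune_epochs=5,
                        learning_rate=0.5, seed=0)
        pretrained = stack_and_attach_head(ds, cfg)
        control = stack_and_attach_head(ds, cfg.replace(pretrain_epochs=0))
        _, costs_p = finetune(pretrained, ds, cfg, np.random.default_rng(1))
        _, costs_c = finetune(control, ds, cfg, np.random.default_rng(1))
        assert costs_p[-1] < costs_c[-1]


class TestPredict:
    def test_rows_sum_to_one(self, rng, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=2, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        model.softmax_weights = rng.normal(size=model.softmax_weights.shape)
        P, _ = predict(model, two_cluster_dataset.features)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_head_uniform_and_ties_to_class_zero(self, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=1, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        P, labels = predict(model, two_cluster_dataset.features)
        np.testing.assert_allclose(P, 0.5)
        assert np.all(labels == 0)

    def test_logit_shift_invariance(self, rng, two_cluster_dataset):
        cfg = SAEConfig(hidden_sizes=(4,), pretrain_epochs=2, seed=0)
        model = stack_and_attach_head(two_cluster_dataset, cfg)
        model.softmax_weights = rng.normal(size=(2, 4))
        P1, _ = predict(model, two_cluster_dataset.features)
        model.softmax_bias = model.softmax_bias + 7.3  # constant on all logits
        P2, _ = predict(model, two_cluster_dataset.features)
        np.testing.assert_allclose(P1, P2, atol=1e-12)


class TestDeterminism:
    def test_identical_seeds_identical_models(self, planted_dataset):
        ds, _ = planted_dataset
        cfg = SAEConfig(hidden_sizes=(6,), pretrain_epochs=5, finetune_epochs=5, seed=3)
        a = SAEClassifier(cfg).fit(ds)
        b = SAEClassifier(cfg).fit(ds)
        np.testing.assert_array_equal(a.model_.layers[0].enc_weights,
                                      b.model_.layers[0].enc_weights)
        np.testing.assert_array_equal(a.model_.softmax_weights, b.model_.softmax_weights)
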