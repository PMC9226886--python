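"""BGCN configuration, forward/backward correctness, training and prediction."""

import numpy as np
import pytest

from bgcn_screen.bgcn_model import (
    BGCNConfig,
    ConfigurationError,
    forward,
    gcn_layer,
    graph_tensors,
    init_bgcn,
    load_checkpoint,
    loss_and_gradients,
    nll_loss,
    predict,
    save_checkpoint,
    train,
    write_history_tsv,
)
from bgcn_screen.bipartite_graph import (
    apply_standardizer,
    build_bipartite_graph,
    fit_standardizer,
)
from bgcn_screen.instruments import AnswerMatrix
from bgcn_screen.synthetic_data import generate_dataset, strong_discrimination_config


def _toy_graph(rng, n_items=3, n_resp=4):
    a_star = rng.normal(size=(n_resp, n_items))
    return build_bipartite_graph(a_star)


class TestConfig:
    def test_defaults_match_study_settings(self):
        cfg = BGCNConfig()
        assert cfg.hidden_dims == (80, 30)
        assert cfg.dropout_p == 0.5
        assert cfg.learning_rate == pytest.approx(1e-2)
        assert cfg.optimizer == "adam"

    @pytest.mark.parametrize("dims", [(80,), (80, 30, 10), ()])
    def test_odd_or_empty_convolution_depth_rejected(self, dims):
        with pytest.raises(ConfigurationError, match="even number of graph-convolution"):
            BGCNConfig(hidden_dims=dims)

    def test_dropout_range(self):
        with pytest.raises(ConfigurationError):
            BGCNConfig(dropout_p=1.0)

    def test_unknown_optimizer(self):
        with pytest.raises(ConfigurationError):
            BGCNConfig(optimizer="lbfgs")


class TestInit:
    def test_shapes_chain_k_to_hidden_to_classes(self):
        params = init_bgcn(BGCNConfig(), n_features=106)
        assert params.conv_weights[0].shape == (106, 80)
        assert params.conv_weights[1].shape == (80, 30)
        assert params.out_weight.shape == (30, 2)
        assert params.out_bias.shape == (2,)

    def test_same_seed_bit_identical(self):
        a = init_bgcn(BGCNConfig(seed=7), n_features=10)
        b = init_bgcn(BGCNConfig(seed=7), n_features=10)
        for wa, wb in zip(a.tensors(), b.tensors()):
            np.testing.assert_array_equal(wa, wb)


class TestGcnLayer:
    def test_identity_adjacency_and_features_returns_theta(self, rng):
        theta = rng.normal(size=(4, 3))
        out = gcn_layer(np.eye(4), np.eye(4), theta, activation="identity")
        np.testing.assert_allclose(out, theta)

    def test_identity_theta_is_pure_propagation(self, rng):
        a_hat = rng.normal(size=(5, 5))
        h = rng.normal(size=(5, 4))
        out = gcn_layer(a_hat, h, np.eye(4), activation="identity")
        np.testing.assert_allclose(out, a_hat @ h)

    def test_matches_elementwise_dense_oracle(self, rng):
        """relu(A H Theta) computed with explicit loops on a 5-node graph."""
        a_hat = rng.normal(size=(5, 5))
        h = rng.normal(size=(5, 3))
        theta = rng.normal(size=(3, 2))
        expected = np.zeros((5, 2))
        for i in range(5):
            for o in range(2):
                acc = 0.0
                for u in range(5):
                    for f in range(3):
                        acc += a_hat[i, u] * h[u, f] * theta[f, o]
                expected[i, o] = max(acc, 0.0)
        np.testing.assert_allclose(gcn_layer(a_hat, h, theta), expected, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            gcn_layer(np.eye(3), np.ones((4, 2)), np.ones((2, 2)))


class TestForward:
    def test_softmax_rows_sum_to_one(self, rng):
        g = _toy_graph(rng)
        params = init_bgcn(BGCNConfig(hidden_dims=(5, 4), seed=1), n_features=3)
        lp = forward(params, g)
        np.testing.assert_allclose(np.exp(lp).sum(axis=1), 1.0, atol=1e-12)

    def test_identical_answer_rows_get_identical_outputs(self, rng):
        a_star = rng.normal(size=(3, 4))
        a_star[2] = a_star[0]
        g = build_bipartite_graph(a_star)
        params = init_bgcn(BGCNConfig(hidden_dims=(6, 4), seed=0), n_features=4)
        lp = forward(params, g)
        np.testing.assert_allclose(lp[2], lp[0], atol=1e-12)

    def test_train_mode_requires_rng(self, rng):
        g = _toy_graph(rng)
        params = init_bgcn(BGCNConfig(hidden_dims=(5, 4)), n_features=3)
        with pytest.raises(ValueError, match="dropout_rng"):
            forward(params, g, mode="train")

    def test_matches_step_by_step_dense_oracle(self, rng):
        """2-item/2-respondent graph against a hand-rolled matrix computation."""
        a_star = np.array([[1.0, -0.5], [0.25, 2.0]])
        g = build_bipartite_graph(a_star)
        params = init_bgcn(BGCNConfig(hidden_dims=(3, 2), seed=5), n_features=2)
        gt = graph_tensors(g)

        h1 = np.maximum(gt.a_hat @ gt.features @ params.conv_weights[0], 0.0)
        h2 = np.maximum(gt.a_hat @ h1 @ params.conv_weights[1], 0.0)
        logits = h2[2:] @ params.out_weight + params.out_bias
        expected = logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))

        np.testing.assert_allclose(forward(params, g), expected, atol=1e-10)

    def test_respondent_permutation_equivariance(self, rng):
        a_star = rng.normal(size=(6, 3))
        params = init_bgcn(BGCNConfig(hidden_dims=(5, 4), seed=2), n_features=3)
        lp = forward(params, build_bipartite_graph(a_star))
        perm = rng.permutation(6)
        lp_perm = forward(params, build_bipartite_graph(a_star[perm]))
        np.testing.assert_allclose(lp_perm, lp[perm], atol=1e-10)


class TestNllLoss:
    def test_uniform_predictor_gives_ln2(self):
        lp = np.log(np.full((4, 2), 0.5))
        assert nll_loss(lp, [0, 1, 0, 1]) == pytest.approx(np.log(2))

    def test_perfect_predictor_gives_zero(self):
        lp = np.log(np.array([[1.0, 1e-300], [1e-300, 1.0]]))
        assert nll_loss(lp, [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_example(self):
        lp = np.log(np.array([[0.8, 0.2], [0.8, 0.2]]))
        # true classes 0 then 1: -(ln 0.8 + ln 0.2)/2
        assert nll_loss(lp, [0, 1]) == pytest.approx(0.9163, abs=1e-4)

    def test_label_outside_binary_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            nll_loss(np.zeros((2, 2)), [0, 2])


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """Central finite differences on every parameter of a small graph."""
        g = _toy_graph(rng, n_items=3, n_resp=3)
        cfg = BGCNConfig(hidden_dims=(4, 2), dropout_p=0.0, seed=3)
        params = init_bgcn(cfg, n_features=3)
        labels = np.array([0, 1, 1])
        gt = graph_tensors(g)

        loss, grads = loss_and_gradients(params, gt, labels)
        eps = 1e-6
        for tensor, grad in zip(params.tensors(), grads):
            flat = tensor.ravel()
            idxs = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for idx in idxs:
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = forward(params, gt)
                up = nll_loss(lp, labels)
                flat[idx] = orig - eps
                lp = forward(params, gt)
                down = nll_loss(lp, labels)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert grad.ravel()[idx] == pytest.approx(
                    fd, rel=1e-5, abs=1e-8
                ), f"gradient mismatch at flat index {idx}"


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_unchanged(self, rng):
        g = _toy_graph(rng)
        cfg = BGCNConfig(hidden_dims=(4, 2), learning_rate=0.0, epochs=3, seed=0)
        params = init_bgcn(cfg, n_features=3)
        trained, _ = train(params, g, [0, 1, 0, 1])
        for a, b in zip(params.tensors(), trained.tensors()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_identical_history(self, rng):
        g = _toy_graph(rng)
        cfg = BGCNConfig(hidden_dims=(4, 2), epochs=5, seed=11)
        h1 = train(init_bgcn(cfg, 3), g, [0, 1, 0, 1])[1]
        h2 = train(init_bgcn(cfg, 3), g, [0, 1, 0, 1])[1]
        assert h1 == h2

    def test_input_params_not_mutated(self, rng):
        g = _toy_graph(rng)
        cfg = BGCNConfig(hidden_dims=(4, 2), epochs=3, seed=0)
        params = init_bgcn(cfg, 3)
        before = [t.copy() for t in params.tensors()]
        train(params, g, [0, 1, 0, 1])
        for a, b in zip(before, params.tensors()):
            np.testing.assert_array_equal(a, b)

    def test_empty_train_mask_rejected(self, rng):
        g = _toy_graph(rng)
        params = init_bgcn(BGCNConfig(hidden_dims=(4, 2)), 3)
        with pytest.raises(ValueError, match="no labeled"):
            train(params, g, [0, 1, 0, 1], train_mask=np.zeros(4, dtype=bool))

    def test_loss_decreases_in_median_over_seeds(self):
        """Median final loss < median initial loss over 5 seeds on synthetic data."""
        first, last = [], []
        for seed in range(5):
            data = generate_dataset(
                strong_discrimination_config(seed=seed, n_positive=30, n_negative=90)
            )
            std = fit_standardizer(data.answers)
            g = build_bipartite_graph(apply_standardizer(std, data.answers))
            cfg = BGCNConfig(epochs=40, seed=seed)
            _, hist = train(init_bgcn(cfg, 106), g, data.labels)
            first.append(hist[0]["loss"])
            last.append(hist[-1]["loss"])
        assert np.median(last) < np.median(first)

    def test_separable_cohort_reaches_high_training_accuracy(self):
        """Strong-discrimination cohort of 600: final train accuracy >= 0.95."""
        data = generate_dataset(
            strong_discrimination_config(seed=0, n_positive=126, n_negative=474)
        )
        std = fit_standardizer(data.answers)
        g = build_bipartite_graph(apply_standardizer(std, data.answers))
        cfg = BGCNConfig(seed=0)
        _, hist = train(init_bgcn(cfg, 106), g, data.labels)
        assert hist[-1]["accuracy"] >= 0.95

    def test_history_written_as_tsv(self, rng, tmp_path):
        g = _toy_graph(rng)
        cfg = BGCNConfig(hidden_dims=(4, 2), epochs=4, seed=0)
        _, hist = train(init_bgcn(cfg, 3), g, [0, 1, 0, 1])
        path = tmp_path / "hist.tsv"
        write_history_tsv(hist, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "epoch\tloss\taccuracy\tf1"
        assert len(lines) == 5


class TestPredict:
    @pytest.fixture
    def trained_setup(self, tiny_bank):
        data = generate_dataset(
            strong_discrimination_config(seed=4, n_positive=20, n_negative=60)
        )
        std = fit_standardizer(data.answers)
        g = build_bipartite_graph(apply_standardizer(std, data.answers))
        cfg = BGCNConfig(epochs=30, seed=4)
        trained, _ = train(init_bgcn(cfg, 106), g, data.labels)
        return trained, std, data

    def test_repeated_prediction_identical(self, trained_setup):
        trained, std, data = trained_setup
        batch = data.answers.subset(range(10))
        r1 = predict(trained, std, data.answers.bank, batch)
        r2 = predict(trained, std, data.answers.bank, batch)
        np.testing.assert_array_equal(r1.labels, r2.labels)
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)

    def test_permutation_equivariance(self, trained_setup, rng):
        trained, std, data = trained_setup
        idx = np.arange(12)
        perm = rng.permutation(12)
        r = predict(trained, std, data.answers.bank, data.answers.subset(idx))
        rp = predict(trained, std, data.answers.bank, data.answers.subset(idx[perm]))
        np.testing.assert_allclose(rp.probabilities, r.probabilities[perm], atol=1e-12)

    def test_exact_tie_resolves_to_healthy(self, trained_setup):
        trained, std, data = trained_setup
        # zeroed output layer makes both logits equal -> probability 0.5/0.5
        tied = trained.copy()
        tied.out_weight[:] = 0.0
        tied.out_bias[:] = 0.0
        r = predict(tied, std, data.answers.bank, data.answers.subset(range(5)))
        np.testing.assert_allclose(r.probabilities, 0.5, atol=1e-12)
        assert (r.labels == 0).all()

    def test_checkpoint_roundtrip_preserves_predictions(self, trained_setup, tmp_path):
        trained, std, data = trained_setup
        path = tmp_path / "ckpt.json"
        save_checkpoint(path, trained, std, data.answers.bank)
        params2, std2, bank2 = load_checkpoint(path)
        batch = data.answers.subset(range(8))
        r1 = predict(trained, std, data.answers.bank, batch)
        r2 = predict(params2, std2, bank2, batch)
        np.testing.assert_allclose(r2.probabilities, r1.probabilities, atol=1e-12)

    def test_bank_mismatch_rejected(self, trained_setup, tiny_bank):
        trained, std, data = trained_setup
        bad = AnswerMatrix(
            codes=np.zeros((1, 3), dtype=int), respondent_ids=["x"], bank=tiny_bank
        )
        with pytest.raises(ValueError):
            predict(trained, std, data.answers.bank, bad)
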