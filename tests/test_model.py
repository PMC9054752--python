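"""NNoD model family: forward map, losses, penalty, training, selection."""

import numpy as np
import pytest

from nnod.metrics import evaluate_scores
from nnod.model import (
    ConceptDecoder,
    DecoderResults,
    ModelConfig,
    _batch_gradients,
    _batch_objective,
    forward,
    grid_search,
    init_params,
    loss_binary,
    loss_multinomial,
    predict_binary,
    predict_multinomial,
    regularization,
    train,
)


def _results(config, params=None):
    return DecoderResults(params=params or init_params(config), config=config)


def _linear_config(p, L, **kw):
    base = dict(
        input_dim=p, n_labels=L, n_hidden=0, activation="identity",
        output_mode="binary", l1_weight=0.0, l2_weight=0.0, dropout_rate=0.0, seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


class TestForward:
    def test_linear_model_is_affine(self):
        cfg = _linear_config(2, 2)
        params = [(np.eye(2), np.zeros(2))]
        out = forward(_results(cfg, params), np.array([1.0, -1.0]))
        assert np.allclose(out, [1.0, -1.0])

    def test_rectifier_zeroes_all_negative_preactivations(self):
        cfg = ModelConfig(input_dim=2, n_labels=3, n_hidden=1, hidden_width=4,
                          activation="rectifier", output_mode="binary",
                          l1_weight=0, l2_weight=0, dropout_rate=0, seed=0)
        W1 = -np.ones((4, 2))
        b1 = np.zeros(4)
        W2 = np.arange(12.0).reshape(3, 4)
        b2 = np.array([1.0, -2.0, 0.5])
        out = forward(_results(cfg, [(W1, b1), (W2, b2)]), np.array([1.0, 2.0]))
        assert np.allclose(out, b2)

    def test_matches_hand_rolled_affine_chain(self, rng):
        cfg = ModelConfig(input_dim=4, n_labels=3, n_hidden=2, hidden_width=5,
                          activation="rectifier", output_mode="binary",
                          l1_weight=0, l2_weight=0, dropout_rate=0, seed=2)
        res = _results(cfg)
        x = rng.normal(size=4)
        h = x
        for W, b in res.params[:-1]:
            h = np.maximum(W @ h + b, 0.0)
        W, b = res.params[-1]
        expected = W @ h + b
        assert np.allclose(forward(res, x), expected, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        res = _results(_linear_config(3, 2))
        with pytest.raises(ValueError):
            forward(res, np.zeros(5))


class TestOutputUnits:
    def test_sigmoid_of_zero_logits_is_half(self):
        cfg = _linear_config(2, 3)
        params = [(np.zeros((3, 2)), np.zeros(3))]
        probs = predict_binary(_results(cfg, params), np.ones(2))
        assert np.allclose(probs, 0.5)

    def test_sigmoid_closed_form_value(self):
        cfg = _linear_config(1, 1)
        params = [(np.array([[1.0]]), np.zeros(1))]
        probs = predict_binary(_results(cfg, params), np.ones(1))
        assert probs[0] == pytest.approx(0.7310586, abs=1e-6)

    def test_softmax_uniform_and_shift_invariant(self, rng):
        cfg = _linear_config(3, 3, output_mode="multinomial")
        params = [(np.eye(3), np.zeros(3))]
        res = _results(cfg, params)
        assert np.allclose(predict_multinomial(res, np.zeros(3)), 1 / 3)
        z = rng.normal(size=3)
        a = predict_multinomial(res, z)
        b = predict_multinomial(res, z + 7.5)
        assert np.allclose(a, b, atol=1e-12)
        assert a.sum() == pytest.approx(1.0)

    def test_softmax_closed_form_value(self):
        cfg = _linear_config(3, 3, output_mode="multinomial")
        params = [(np.eye(3), np.zeros(3))]
        probs = predict_multinomial(_results(cfg, params), np.array([1.0, 2.0, 3.0]))
        assert np.allclose(probs, [0.0900, 0.2447, 0.6652], atol=1e-4)

    def test_output_mode_mismatch_rejected(self):
        res = _results(_linear_config(2, 2))
        with pytest.raises(ValueError):
            predict_multinomial(res, np.zeros(2))


class TestLosses:
    def test_binary_hand_computed_value(self):
        value = loss_binary(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert value == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_binary_perfect_prediction_is_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert loss_binary(y, y) < 1e-5

    def test_binary_decreases_toward_target(self):
        y = np.array([1.0, 0.0])
        losses = [loss_binary(y, np.array([p, 1 - p])) for p in (0.5, 0.7, 0.9, 0.99)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_multinomial_hand_computed_value(self):
        value = loss_multinomial(np.array([1.0, 1.0, 0.0]), np.array([0.5, 0.5, 0.0]))
        assert value == pytest.approx(np.log(2), abs=1e-6)

    def test_multinomial_matched_one_hot_is_near_zero(self):
        y = np.array([1.0, 0.0, 0.0])
        yhat = np.array([1.0 - 2e-7, 1e-7, 1e-7])
        assert loss_multinomial(y, yhat) < 1e-5

    def test_multinomial_scale_invariance_in_targets(self, rng):
        y = np.array([1.0, 1.0, 0.0, 1.0])
        yhat = rng.dirichlet(np.ones(4))
        assert loss_multinomial(y, yhat) == pytest.approx(loss_multinomial(3 * y, yhat))

    def test_multinomial_all_zero_target_rejected(self):
        with pytest.raises(ValueError):
            loss_multinomial(np.zeros(3), np.full(3, 1 / 3))

    def test_binary_equals_sum_of_independent_label_losses(self, rng):
        y = (rng.random(6) < 0.5).astype(float)
        yhat = rng.uniform(0.01, 0.99, 6)
        total = sum(
            -(y[l] * np.log(yhat[l]) + (1 - y[l]) * np.log(1 - yhat[l]))
            for l in range(6)
        )
        assert loss_binary(y, yhat) == pytest.approx(total, abs=1e-9)


class TestRegularization:
    def test_hand_computed_value(self):
        params = [(np.array([[2.0]]), np.zeros(1))]
        assert regularization(params, 0.001, 0.001) == pytest.approx(0.006)

    def test_zero_weights_give_zero(self):
        params = [(np.zeros((3, 2)), np.ones(3))]  # biases excluded
        assert regularization(params, 0.5, 0.5) == 0.0

    def test_sign_flip_invariance(self, rng):
        W = rng.normal(size=(4, 3))
        a = regularization([(W, np.zeros(4))], 0.01, 0.02)
        b = regularization([(-W, np.zeros(4))], 0.01, 0.02)
        assert a == pytest.approx(b)


def _fd_max_rel_err(n_hidden, activation, output_mode, rng):
    cfg = ModelConfig(input_dim=5, n_labels=4, n_hidden=n_hidden, hidden_width=6,
                      activation=activation, output_mode=output_mode,
                      l1_weight=1e-3, l2_weight=1e-3, dropout_rate=0.0, seed=3)
    X = rng.normal(size=(7, 5))
    Y = (rng.random((7, 4)) < 0.4).astype(float)
    Y[Y.sum(axis=1) == 0, 0] = 1.0
    T = Y if output_mode == "binary" else Y / Y.sum(axis=1, keepdims=True)
    # perturb away from zero so the l1 subgradient is well defined
    params = [
        (W + rng.normal(0, 0.1, W.shape), b + rng.normal(0, 0.1, b.shape))
        for W, b in init_params(cfg)
    ]
    grads = _batch_gradients(params, X, T, cfg, None)
    h = 1e-6
    worst = 0.0
    for li, (W, b) in enumerate(params):
        for arr, g in ((W, grads[li][0]), (b, grads[li][1])):
            flat = arr.reshape(-1)
            gflat = np.asarray(g).reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 8)):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = _batch_objective(params, X, T, cfg)
                flat[idx] = orig - h
                lm = _batch_objective(params, X, T, cfg)
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                # relative-or-absolute hybrid: central-difference roundoff is
                # ~1e-10 absolute, so near-zero gradients are compared on an
                # absolute scale instead of blowing up the relative error
                denom = max(abs(fd), abs(gflat[idx]), 1e-4)
                worst = max(worst, abs(fd - gflat[idx]) / denom)
    return worst


class TestGradients:
    @pytest.mark.parametrize("n_hidden,activation,output_mode", [
        (0, "identity", "binary"),
        (1, "rectifier", "binary"),
        (2, "rectifier", "multinomial"),
        (3, "identity", "multinomial"),
    ])
    def test_analytic_gradients_match_finite_differences(self, n_hidden, activation,
                                                         output_mode, rng):
        assert _fd_max_rel_err(n_hidden, activation, output_mode, rng) < 1e-4


@pytest.fixture(scope="module")
def separable_toy():
    rng = np.random.default_rng(4)
    n = 200
    centers = np.array([[3.0, 0.0, 0.0], [0.0, 3.0, 0.0]])
    labels = rng.integers(0, 2, n)
    X = centers[labels] + rng.normal(0, 0.3, (n, 3))
    Y = np.column_stack([labels == 0, labels == 1]).astype(float)
    return X, Y


class TestTraining:
    def test_loss_decreases_and_separable_data_fits_perfectly(self, separable_toy):
        X, Y = separable_toy
        cfg = _linear_config(3, 2)
        res = train(cfg, X, Y, epochs=60, batch_size=32, learning_rate=1e-2)
        assert res.history[5] < res.history[0]
        report = evaluate_scores(Y, res.decision_function(X), k=1)
        assert report.macro_auc == pytest.approx(1.0)

    def test_training_is_bit_reproducible(self, separable_toy):
        X, Y = separable_toy
        cfg = _linear_config(3, 2, l1_weight=1e-3, l2_weight=1e-3)
        a = train(cfg, X, Y, epochs=10)
        b = train(cfg, X, Y, epochs=10)
        for (Wa, ba), (Wb, bb) in zip(a.params, b.params):
            assert np.array_equal(Wa, Wb) and np.array_equal(ba, bb)

    def test_matches_unregularized_logistic_fit(self, rng):
        from sklearn.linear_model import LogisticRegression

        n = 300
        X = rng.normal(size=(n, 6))
        w = rng.normal(size=(6, 3))
        Y = (rng.random((n, 3)) < 1 / (1 + np.exp(-(X @ w)))).astype(float)
        cfg = _linear_config(6, 3)
        res = train(cfg, X[:200], Y[:200], epochs=300, batch_size=64, learning_rate=1e-2)
        ours = evaluate_scores(Y[200:], res.decision_function(X[200:]), k=1).macro_auc
        sk_scores = np.column_stack([
            LogisticRegression(C=1e6, max_iter=3000).fit(X[:200], Y[:200, l])
            .decision_function(X[200:])
            for l in range(3)
        ])
        theirs = evaluate_scores(Y[200:], sk_scores, k=1).macro_auc
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_l1_path_shrinks_weight_norm(self, separable_toy):
        X, Y = separable_toy
        norms = []
        for l1 in (0.0, 0.01, 0.1, 1.0):
            cfg = _linear_config(3, 2, l1_weight=l1)
            res = train(cfg, X, Y, epochs=150, batch_size=64, learning_rate=1e-2)
            norms.append(sum(np.abs(W).sum() for W, _ in res.params))
        assert all(a >= b - 1e-6 for a, b in zip(norms, norms[1:]))

    def test_dropout_training_still_learns(self, separable_toy):
        X, Y = separable_toy
        cfg = ModelConfig(input_dim=3, n_labels=2, n_hidden=1, hidden_width=16,
                          activation="rectifier", output_mode="binary",
                          l1_weight=0, l2_weight=0, dropout_rate=0.2, seed=0)
        res = train(cfg, X, Y, epochs=80, batch_size=32, learning_rate=1e-2)
        report = evaluate_scores(Y, res.decision_function(X), k=1)
        assert report.macro_auc > 0.95

    def test_empty_data_rejected(self):
        cfg = _linear_config(3, 2)
        with pytest.raises(ValueError):
            train(cfg, np.zeros((0, 3)), np.zeros((0, 2)))


class TestDecoderObjects:
    def test_fit_returns_results_with_labels_and_summary(self, separable_toy):
        import pandas as pd

        X, Y = separable_toy
        Ydf = pd.DataFrame(Y, columns=["left", "right"])
        dec = ConceptDecoder(X, Ydf, _linear_config(3, 2))
        res = dec.fit(epochs=20)
        assert res.label_names == ["left", "right"]
        assert res.label_index("right") == 1
        text = res.summary()
        assert "binary" in text and "3 -> 2" in text

    def test_save_load_roundtrip(self, tmp_path, separable_toy):
        X, Y = separable_toy
        res = train(_linear_config(3, 2), X, Y, epochs=5)
        res.save(tmp_path / "ckpt")
        back = DecoderResults.load(tmp_path / "ckpt")
        assert np.allclose(back.decision_function(X), res.decision_function(X))
        assert back.config == res.config


class TestGridSearch:
    def test_single_config_is_returned(self, separable_toy):
        X, Y = separable_toy
        cfg = _linear_config(3, 2)
        best, res, table = grid_search([cfg], X, Y, X, Y, epochs=20)
        assert best is cfg
        assert len(table) == 1

    def test_over_penalized_config_never_wins(self, separable_toy):
        X, Y = separable_toy
        good = _linear_config(3, 2)
        bad = _linear_config(3, 2, l1_weight=1e3)
        best, _, table = grid_search([good, bad], X, Y, X, Y, epochs=60,
                                     learning_rate=1e-2)
        assert best is good
        assert len(table) == 2
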