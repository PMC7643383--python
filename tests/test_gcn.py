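"""Spectral GCN: forward pass, gradients, training, prediction."""

import numpy as np
import pandas as pd
import pytest

from ecgcn.exceptions import ValidationError
from ecgcn.gcn import (
    TrainConfig,
    cheb_basis,
    gcn_forward,
    gradient_check,
    init_gcn,
    loss_and_gradients,
    predict,
    train_gcn,
)
from ecgcn.population_graph import PopulationGraph, build_adjacency, spectral_operator


def _random_operator(n, rng, density=0.6):
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    graph = PopulationGraph(
        adjacency=w,
        sigma=1.0,
        gamma=2.0,
        phenotypes=pd.DataFrame({"age": [30] * n, "gender": ["F"] * n}),
        feature_matrix=np.zeros((n, 1)),
    )
    return spectral_operator(graph)


class TestInit:
    def test_seed_reproducibility(self):
        a = init_gcn(5, [16], K=3, seed=11)
        b = init_gcn(5, [16], K=3, seed=11)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.theta, lb.theta)

    def test_third_order_chebyshev_shapes(self):
        model = init_gcn(5, [16], K=3)
        assert model.layers[0].theta.shape == (4, 5, 16)
        assert model.layers[1].theta.shape == (4, 16, 2)

    def test_no_hidden_layer_degenerate_model(self):
        model = init_gcn(7, [], K=2)
        assert len(model.layers) == 1
        assert model.layers[0].theta.shape == (3, 7, 2)

    def test_negative_k_rejected(self):
        with pytest.raises(ValidationError):
            init_gcn(5, [16], K=-1)


class TestForward:
    def test_k0_single_layer_is_pointwise_softmax(self, rng):
        n = 6
        op = _random_operator(n, rng)
        model = init_gcn(4, [], K=0, seed=0)
        f = rng.standard_normal((n, 4))
        probs, _ = gcn_forward(model, op, f)
        logits = f @ model.layers[0].theta[0] + model.layers[0].bias
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        np.testing.assert_allclose(probs, e / e.sum(axis=1, keepdims=True), atol=1e-12)

    def test_isolated_vertices_do_not_mix(self, rng):
        n = 5
        graph = PopulationGraph(
            adjacency=np.zeros((n, n)),
            sigma=1.0,
            gamma=2.0,
            phenotypes=pd.DataFrame({"age": [30] * n, "gender": ["F"] * n}),
            feature_matrix=np.zeros((n, 1)),
        )
        op = spectral_operator(graph)
        model = init_gcn(3, [4], K=3, seed=2)
        f = rng.standard_normal((n, 3))
        probs, _ = gcn_forward(model, op, f)
        f2 = f.copy()
        f2[2] += 10.0
        probs2, _ = gcn_forward(model, op, f2)
        others = [i for i in range(n) if i != 2]
        np.testing.assert_allclose(probs2[others], probs[others], atol=1e-12)
        assert not np.allclose(probs2[2], probs[2])

    def test_graph_automorphism_gives_identical_rows(self, rng):
        # vertices 0 and 1 are swappable: same features, same neighbourhoods
        w = np.array(
            [
                [0.0, 0.0, 1.0, 2.0],
                [0.0, 0.0, 1.0, 2.0],
                [1.0, 1.0, 0.0, 0.5],
                [2.0, 2.0, 0.5, 0.0],
            ]
        )
        graph = PopulationGraph(
            adjacency=w,
            sigma=1.0,
            gamma=2.0,
            phenotypes=pd.DataFrame({"age": [30] * 4, "gender": ["F"] * 4}),
            feature_matrix=np.zeros((4, 1)),
        )
        op = spectral_operator(graph)
        f = rng.standard_normal((4, 3))
        f[1] = f[0]
        model = init_gcn(3, [5], K=3, seed=4)
        probs, _ = gcn_forward(model, op, f)
        np.testing.assert_allclose(probs[0], probs[1], atol=1e-10)

    def test_softmax_rows_sum_to_one(self, rng):
        op = _random_operator(7, rng)
        model = init_gcn(4, [6], K=2, seed=1)
        probs, _ = gcn_forward(model, op, rng.standard_normal((7, 4)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-10)


class TestChebyshevEquivalence:
    def test_recurrence_matches_eigendecomposition(self, rng):
        # Eq-style spectral filtering: U T_k(Lambda) U^T F == T_k(L~) F
        n, k_order = 8, 3
        op = _random_operator(n, rng)
        lam, u = np.linalg.eigh(op.laplacian_scaled)
        basis = cheb_basis(op, k_order)
        f = rng.standard_normal((n, 4))
        # Chebyshev polynomials of the eigenvalues
        tk_lam = [np.ones_like(lam), lam.copy()]
        for _ in range(2, k_order + 1):
            tk_lam.append(2 * lam * tk_lam[-1] - tk_lam[-2])
        for k in range(k_order + 1):
            spectral = u @ np.diag(tk_lam[k]) @ u.T @ f
            np.testing.assert_allclose(basis[k] @ f, spectral, atol=1e-8)


class TestGradients:
    def test_gradient_check_small_instance(self, rng):
        op = _random_operator(6, rng)
        model = init_gcn(3, [4], K=2, seed=5)
        f = rng.standard_normal((6, 3))
        y = np.array([0, 1, 0, 1, 1, 0])
        err = gradient_check(model, op, f, y, epsilon=1e-5)
        assert err < 1e-5

    def test_gradient_check_with_weight_decay(self, rng):
        op = _random_operator(5, rng)
        model = init_gcn(2, [], K=1, seed=6)
        f = rng.standard_normal((5, 2))
        y = np.array([0, 1, 0, 1, 1])
        err = gradient_check(model, op, f, y, epsilon=1e-5, weight_decay=5e-4)
        assert err < 1e-5

    def test_k0_matches_softmax_regression_gradient(self, rng):
        # K=0, no hidden layer: exactly multinomial logistic regression
        n = 6
        graph = PopulationGraph(
            adjacency=np.zeros((n, n)),
            sigma=1.0,
            gamma=2.0,
            phenotypes=pd.DataFrame({"age": [30] * n, "gender": ["F"] * n}),
            feature_matrix=np.zeros((n, 1)),
        )
        op = spectral_operator(graph)
        model = init_gcn(3, [], K=0, seed=7)
        f = rng.standard_normal((n, 3))
        y = np.array([0, 1, 1, 0, 1, 0])
        mask = np.ones(n, bool)
        _, grads, probs = loss_and_gradients(model, op, f, y, mask)
        onehot = np.eye(2)[y]
        expected = f.T @ (probs - onehot) / n
        np.testing.assert_allclose(grads[0][0][0], expected, atol=1e-8)
        np.testing.assert_allclose(grads[0][1], (probs - onehot).sum(0) / n, atol=1e-8)

    def test_zero_features_zero_weight_gradient(self, rng):
        op = _random_operator(5, rng)
        model = init_gcn(3, [], K=2, seed=8)
        f = np.zeros((5, 3))
        y = np.array([0, 1, 0, 1, 1])
        _, grads, _ = loss_and_gradients(model, op, f, y, np.ones(5, bool))
        np.testing.assert_allclose(grads[0][0], 0.0, atol=1e-12)
        assert np.any(grads[0][1] != 0)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    n = 30
    y = np.array([0] * 15 + [1] * 15)
    f = rng.standard_normal((n, 6)) + 5.0 * y[:, None] * np.ones(6)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if y[i] == y[j] and rng.random() < 0.4:
                w[i, j] = w[j, i] = 1.0
    graph = PopulationGraph(
        adjacency=w,
        sigma=1.0,
        gamma=2.0,
        phenotypes=pd.DataFrame({"age": [30] * n, "gender": ["F"] * n}),
        feature_matrix=np.zeros((n, 1)),
    )
    return spectral_operator(graph), f, y


class TestTraining:
    def test_separable_data_fits_training_set(self, separable):
        op, f, y = separable
        mask = np.zeros(len(y), bool)
        mask[:10] = mask[15:25] = True
        model = init_gcn(6, [16], K=3, seed=0)
        model, losses = train_gcn(model, op, f, y, mask, TrainConfig(seed=0))
        pred, _ = predict(model, op, f)
        assert np.all(pred[mask] == y[mask])

    def test_heldout_accuracy_on_separable_data(self, separable):
        op, f, y = separable
        mask = np.zeros(len(y), bool)
        mask[:10] = mask[15:25] = True
        model = init_gcn(6, [16], K=3, seed=0)
        model, _ = train_gcn(model, op, f, y, mask, TrainConfig(seed=0))
        pred, _ = predict(model, op, f)
        assert (pred[~mask] == y[~mask]).mean() > 0.9

    def test_loss_decreases_early(self, separable):
        op, f, y = separable
        mask = np.ones(len(y), bool)
        model = init_gcn(6, [16], K=3, seed=0)
        _, losses = train_gcn(
            model, op, f, y, mask, TrainConfig(seed=0, dropout=0.0, epochs=10)
        )
        assert losses[-1] < losses[0]

    def test_strong_weight_decay_shrinks_parameters(self, separable):
        op, f, y = separable
        mask = np.ones(len(y), bool)
        model = init_gcn(6, [16], K=3, seed=0)
        init_max = max(np.abs(l.theta).max() for l in model.layers)
        trained, _ = train_gcn(
            model, op, f, y, mask,
            TrainConfig(seed=0, weight_decay=1e3, learning_rate=1e-4, epochs=200),
        )
        final_max = max(np.abs(l.theta).max() for l in trained.layers)
        assert final_max < 0.1 * init_max

    def test_training_is_deterministic(self, separable):
        op, f, y = separable
        mask = np.ones(len(y), bool)
        runs = []
        for _ in range(2):
            model = init_gcn(6, [16], K=3, seed=3)
            trained, losses = train_gcn(model, op, f, y, mask, TrainConfig(seed=3))
            runs.append((trained, losses))
        for la, lb in zip(runs[0][0].layers, runs[1][0].layers):
            np.testing.assert_array_equal(la.theta, lb.theta)
        assert runs[0][1] == runs[1][1]

    def test_single_class_mask_rejected(self, separable):
        op, f, y = separable
        mask = np.zeros(len(y), bool)
        mask[:5] = True  # only class 0
        model = init_gcn(6, [16], K=3, seed=0)
        with pytest.raises(ValidationError, match="both classes"):
            train_gcn(model, op, f, y, mask, TrainConfig(seed=0))


class TestPredict:
    def test_repeated_calls_identical(self, rng):
        op = _random_operator(6, rng)
        model = init_gcn(3, [4], K=2, seed=9)
        f = rng.standard_normal((6, 3))
        l1, p1 = predict(model, op, f)
        l2, p2 = predict(model, op, f)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-10)
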