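"""Base-learner primitives, architecture rules, and the training loop."""

import numpy as np
import pytest
import statsmodels.api as sm

from stackprs.dnn_base import (
    BaseModelSpec,
    bce_loss,
    build_network,
    grid_search,
    hidden_widths,
    leaky_relu,
    logistic,
    mse_loss,
    predict,
    train_base,
)


# -- primitives --------------------------------------------------------------


@pytest.mark.parametrize("x,alpha,expected", [(3.0, 0.01, 3.0), (-2.0, 0.01, -0.02), (0.0, 0.5, 0.0)])
def test_leaky_relu_values(x, alpha, expected):
    assert leaky_relu(x, alpha) == pytest.approx(expected)


def test_logistic_properties(rng):
    assert logistic(0.0) == 0.5
    x = rng.normal(0, 3, 100)
    np.testing.assert_allclose(logistic(x), 1.0 - logistic(-x), atol=1e-14)
    assert logistic(-800.0) < 1e-6  # no overflow
    assert logistic(800.0) == pytest.approx(1.0)


def test_bce_values(rng):
    assert bce_loss(np.array([1.0, 0.0]), np.array([1 - 1e-12, 1e-12])) == pytest.approx(0.0, abs=1e-9)
    assert bce_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(np.log(2))
    y = (rng.random(50) < 0.5).astype(float)
    p = rng.uniform(0.01, 0.99, 50)
    direct = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert bce_loss(y, p) == pytest.approx(direct, abs=1e-12)


def test_mse_values(rng):
    y = rng.normal(size=30)
    assert mse_loss(y, y) == 0.0
    assert mse_loss(np.zeros(2), np.array([1.0, -1.0])) == 1.0
    yhat = rng.normal(size=30)
    assert mse_loss(y, yhat) == pytest.approx(np.mean((y - yhat) ** 2), abs=1e-12)


# -- architecture ------------------------------------------------------------


def test_width_chain():
    assert hidden_widths(BaseModelSpec(depth=1, width_divisors=(2,)), 10) == [5]
    assert hidden_widths(BaseModelSpec(depth=3, width_divisors=(4, 4, 4)), 100) == [25, 6, 1]
    with pytest.raises(ValueError, match="width"):
        hidden_widths(BaseModelSpec(depth=4, width_divisors=(4, 4, 4, 4)), 100)


def test_spec_validation():
    with pytest.raises(ValueError, match="depth"):
        BaseModelSpec(depth=5, width_divisors=(1,) * 5)
    with pytest.raises(ValueError, match="divisor"):
        BaseModelSpec(depth=1, width_divisors=(5,))
    with pytest.raises(ValueError, match="per hidden layer"):
        BaseModelSpec(depth=2, width_divisors=(2,))


def test_parameter_count_matches_formula():
    spec = BaseModelSpec(depth=2, width_divisors=(2, 2), use_batchnorm=True, use_dropout=True)
    net = build_network(spec, 10, "binary")
    # affine 10->5 (55) + bn (10) + affine 5->2 (12) + bn (4) + out 2->1 (3)
    assert net.n_parameters() == 55 + 10 + 12 + 4 + 3


def test_network_shapes_and_inference_determinism(rng):
    spec = BaseModelSpec(depth=2, width_divisors=(2, 2), seed=3)
    net = build_network(spec, 12, "binary")
    X = rng.normal(size=(7, 12))
    out1, _ = net.forward(X, training=False)
    out2, _ = net.forward(X, training=False)
    np.testing.assert_array_equal(out1, out2)
    assert out1.shape == (7,)
    assert np.all((out1 > 0) & (out1 < 1))


# -- training ----------------------------------------------------------------


def _toy_binary(n=200, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    eta = 3.0 * X[:, 0] - 2.0 * X[:, 1]
    if separable:
        y = (eta > 0).astype(float)
    else:
        y = (rng.random(n) < logistic(eta)).astype(float)
    return X, y


def test_training_reduces_separable_loss():
    X, y = _toy_binary(separable=True)
    spec = BaseModelSpec(depth=1, width_divisors=(1,), use_dropout=False,
                         use_batchnorm=False, max_epochs=200, early_stop_patience=200,
                         batch_size=8, full_batch_below=0, seed=5)
    model = train_base(X[:150], y[:150], X[150:], y[150:], spec, "binary")
    assert bce_loss(y[:150], predict(model, X[:150])) < 0.1


def test_zero_epoch_budget_returns_initial_weights():
    X, y = _toy_binary(100)
    spec = BaseModelSpec(depth=1, width_divisors=(2,), max_epochs=0, seed=1)
    model = train_base(X[:80], y[:80], X[80:], y[80:], spec, "binary")
    fresh = build_network(spec, 4, "binary")
    np.testing.assert_array_equal(model.network.layers[0]["W"], fresh.layers[0]["W"])
    assert model.epochs_run == 0


def test_same_seed_trains_identically():
    X, y = _toy_binary(300, seed=2)
    spec = BaseModelSpec(depth=2, width_divisors=(2, 1), max_epochs=30, seed=11)
    m1 = train_base(X[:240], y[:240], X[240:], y[240:], spec, "binary")
    m2 = train_base(X[:240], y[:240], X[240:], y[240:], spec, "binary")
    np.testing.assert_array_equal(m1.network.out_W, m2.network.out_W)
    for l1, l2 in zip(m1.network.layers, m2.network.layers):
        np.testing.assert_array_equal(l1["W"], l2["W"])
    np.testing.assert_array_equal(predict(m1, X), predict(m2, X))


def test_quantitative_head_unbounded(rng):
    X = rng.normal(size=(200, 6))
    y = 5.0 * X[:, 0] + rng.normal(size=200)
    spec = BaseModelSpec(depth=0, width_divisors=(), use_dropout=False,
                         use_batchnorm=False, max_epochs=400, early_stop_patience=50,
                         learning_rate=1e-2, batch_size=16, full_batch_below=0, seed=7)
    model = train_base(X[:160], y[:160], X[160:], y[160:], spec, "quantitative")
    pred = predict(model, X[160:])
    assert pred.max() > 1.5  # identity head, not squashed
    assert mse_loss(y[160:], pred) < 2.0


def test_degenerate_network_matches_logistic_oracle():
    """Affine + logistic trained by Adam reaches the logistic-regression optimum."""
    rng = np.random.default_rng(42)
    n, d = 1200, 10
    X = rng.normal(size=(n, d))
    beta = rng.normal(0, 0.5, d)
    y = (rng.random(n) < logistic(X @ beta - 0.2)).astype(float)
    tr, va = np.arange(0, 960), np.arange(960, n)
    spec = BaseModelSpec(depth=0, width_divisors=(), use_dropout=False, use_batchnorm=False,
                         max_epochs=2000, early_stop_patience=50, seed=1)
    model = train_base(X[tr], y[tr], X[va], y[va], spec, "binary")
    net_bce = bce_loss(y[va], predict(model, X[va]))

    mu, sd = X[tr].mean(0), X[tr].std(0)
    res = sm.Logit(y[tr], sm.add_constant((X[tr] - mu) / sd)).fit(disp=0)
    oracle_bce = bce_loss(y[va], res.predict(sm.add_constant((X[va] - mu) / sd)))
    assert net_bce <= oracle_bce * 1.05


def test_gradients_match_finite_differences():
    """Backprop through batch-norm + leaky ReLU + logistic checked numerically."""
    rng = np.random.default_rng(9)
    X = rng.normal(size=(12, 5))
    y = (rng.random(12) < 0.5).astype(float)
    spec = BaseModelSpec(depth=2, width_divisors=(1, 2), use_dropout=False,
                         use_batchnorm=True, seed=4)
    net = build_network(spec, 5, "binary")

    def loss():
        p, _ = net.forward(X, training=True)
        return bce_loss(y, p)

    _, cache = net.forward(X, training=True)
    grads = net.backward(cache, y)
    eps = 1e-6
    for li, name in [(0, "W"), (0, "gamma"), (1, "b"), (1, "beta")]:
        param = net.layers[li][name]
        flat_idx = (0,) if param.ndim == 1 else (0, 0)
        orig = param[flat_idx]
        param[flat_idx] = orig + eps
        up = loss()
        param[flat_idx] = orig - eps
        down = loss()
        param[flat_idx] = orig
        numeric = (up - down) / (2 * eps)
        analytic = grads[li][name][flat_idx]
        assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-8)


# -- grid search -------------------------------------------------------------


def test_grid_search_singleton_and_table():
    X, y = _toy_binary(400, seed=3)
    tr, va = np.arange(0, 320), np.arange(320, 400)
    specs = [
        BaseModelSpec(depth=1, width_divisors=(2,), use_dropout=False, max_epochs=30, seed=1),
        BaseModelSpec(depth=1, width_divisors=(2,), use_dropout=True, max_epochs=30, seed=1),
        BaseModelSpec(depth=2, width_divisors=(2, 2), use_dropout=False, max_epochs=30, seed=1),
        BaseModelSpec(depth=2, width_divisors=(2, 2), use_dropout=True, max_epochs=30, seed=1),
    ]
    best, table = grid_search(X[tr], y[tr], X[va], y[va], specs, "binary")
    assert len(table) == 4 and not table["skipped"].any()
    assert best.val_metric == pytest.approx(table["val_metric"].max())

    only, table1 = grid_search(X[tr], y[tr], X[va], y[va], specs[:1], "binary")
    assert only.spec == specs[0] and len(table1) == 1


def test_grid_search_skips_collapsed_widths():
    X, y = _toy_binary(100, seed=4)
    specs = [
        BaseModelSpec(depth=4, width_divisors=(4, 4, 4, 4), max_epochs=5, seed=1),  # collapses
        BaseModelSpec(depth=1, width_divisors=(2,), max_epochs=5, seed=1),
    ]
    best, table = grid_search(X[:80], y[:80], X[80:], y[80:], specs, "binary")
    assert table["skipped"].tolist() == [True, False]
    assert best.spec == specs[1]
    with pytest.raises(ValueError, match="invalid"):
        grid_search(X[:80], y[:80], X[80:], y[80:], specs[:1], "binary")
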