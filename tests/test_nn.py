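"""The numpy network: shapes, gradients, early stopping, determinism."""

import numpy as np
import pytest

import protlife.nn as nn
from protlife.nn import (
    Adam,
    BuildError,
    EarlyStopper,
    HalfLifeNet,
    bce_with_logits,
    projection_output_dim,
    train_network,
)


def _toy_net(**kw):
    defaults = dict(
        d_local=14, L_padded=20, feature_dim=3, kernel_size=3, n_filters=2,
        n_layers=1, n_units=8, dropout=0.0, pool_size=2, seed=5,
    )
    defaults.update(kw)
    return HalfLifeNet(**defaults)


class TestShapes:
    def test_projection_dim_formula_matches_forward_pass(self):
        # closed form: two (conv valid, pool /2) blocks, flattened
        d_local, L, k, f = 30, 64, 7, 8
        want = projection_output_dim(d_local, L, k, f)
        net = HalfLifeNet(d_local, L, feature_dim=4, kernel_size=k, n_filters=f,
                          n_layers=1, n_units=16, dropout=0.0, seed=0)
        assert net.proj_dim == want
        x = np.random.default_rng(0).standard_normal((3, 1, d_local, L))
        logits = net.forward(x, np.zeros((3, 4)))
        assert logits.shape == (3,)

    def test_kernel_too_large_is_build_error(self):
        with pytest.raises(BuildError):
            HalfLifeNet(d_local=8, L_padded=64, feature_dim=2, kernel_size=9,
                        n_filters=2, n_layers=1, n_units=4, dropout=0.0, seed=0)

    def test_input_dim_units_resolve_to_concatenated_width(self):
        net = _toy_net(n_units="input_dim", feature_dim=5)
        assert net.dense_layers[0].W.shape == (net.proj_dim + 5, net.proj_dim + 5)

    def test_forward_output_in_unit_interval_and_batched(self, rng):
        net = _toy_net()
        x = rng.standard_normal((7, 1, 14, 20))
        f = rng.standard_normal((7, 3))
        probs = net.predict_proba(x.astype(np.float32), f.astype(np.float32))
        assert probs.shape == (7,)
        assert np.all((probs > 0) & (probs < 1))


class TestGradients:
    def test_backprop_matches_finite_differences(self, monkeypatch):
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        net = _toy_net()
        rng = np.random.default_rng(2)
        x = rng.standard_normal((6, 1, 14, 20))
        feats = rng.standard_normal((6, 3))
        y = rng.integers(0, 2, size=6).astype(float)

        def loss():
            return bce_with_logits(net.forward(x, feats, train=False), y)

        logits = net.forward(x, feats, train=True)
        net.backward((nn._sigmoid(logits) - y) / len(y))
        grads = net.gradients()
        layers = net._param_layers()
        eps = 1e-6
        for li, layer in enumerate(layers):
            W = layer.W
            flat = W.reshape(-1)
            for j in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                hi = loss()
                flat[j] = orig - eps
                lo = loss()
                flat[j] = orig
                numeric = (hi - lo) / (2 * eps)
                analytic = grads[2 * li].reshape(-1)[j]
                assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestEarlyStopping:
    def test_improvement_only_at_epoch_one_stops_at_epoch_six(self):
        stopper = EarlyStopper(patience=5)
        losses = [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6]
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 6  # 1 + patience
        assert stopper.best_epoch == 1

    def test_counter_resets_on_improvement(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1, 1.0)
        assert not stopper.update(2, 1.1)
        assert not stopper.update(3, 0.9)  # reset
        assert not stopper.update(4, 0.95)
        assert stopper.update(5, 0.95)


def _separable_problem(rng, n=400, d_local=14, L=20):
    x = rng.standard_normal((n, 1, d_local, L)).astype(np.float32)
    y = rng.integers(0, 2, size=n).astype(float)
    feats = rng.standard_normal((n, 4)).astype(np.float32)
    feats[:, 0] += 3.0 * (2 * y - 1)  # 3-SD class shift on one feature
    return x, feats, y


class TestTraining:
    def test_learns_linearly_separable_features(self):
        rng = np.random.default_rng(0)
        x, feats, y = _separable_problem(rng)
        net = _toy_net(feature_dim=4, dropout=0.1, seed=1)
        train_network(net, x[:300], feats[:300], y[:300], x[300:], feats[300:],
                      y[300:], learning_rate=1e-3, max_epochs=15, batch_size=32)
        pred = (net.predict_proba(x[:300], feats[:300]) >= 0.5).astype(float)
        tp = np.sum((pred == 1) & (y[:300] == 1))
        tn = np.sum((pred == 0) & (y[:300] == 0))
        fp = np.sum((pred == 1) & (y[:300] == 0))
        fn = np.sum((pred == 0) & (y[:300] == 1))
        mcc = (tp * tn - fp * fn) / np.sqrt(
            (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        assert mcc >= 0.95

    def test_same_seed_identical_weights(self):
        rng = np.random.default_rng(3)
        x, feats, y = _separable_problem(rng, n=80)
        runs = []
        for _ in range(2):
            net = _toy_net(feature_dim=4, dropout=0.2, seed=9)
            train_network(net, x[:60], feats[:60], y[:60], x[60:], feats[60:],
                          y[60:], max_epochs=4, batch_size=16)
            runs.append(net.get_weights())
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_training_log_and_best_weights_restored(self):
        rng = np.random.default_rng(4)
        x, feats, y = _separable_problem(rng, n=100)
        net = _toy_net(feature_dim=4, seed=2)
        log = train_network(net, x[:70], feats[:70], y[:70], x[70:], feats[70:],
                            y[70:], max_epochs=8, batch_size=16)
        assert log.epochs == list(range(1, len(log.epochs) + 1))
        assert log.stop_epoch == int(np.argmin(log.val_loss)) + 1

    def test_empty_split_rejected(self):
        net = _toy_net()
        empty = np.empty((0, 1, 14, 20)), np.empty((0, 3)), np.empty(0)
        with pytest.raises(ValueError):
            train_network(net, *empty, *empty)

    def test_batching_invariance_of_predictions(self, rng):
        net = _toy_net(seed=8)
        x = rng.standard_normal((11, 1, 14, 20)).astype(np.float32)
        f = rng.standard_normal((11, 3)).astype(np.float32)
        p1 = net.predict_proba(x, f, batch_size=1)
        p64 = net.predict_proba(x, f, batch_size=64)
        np.testing.assert_allclose(p1, p64, atol=1e-6)


class TestAdam:
    def test_first_step_size_is_learning_rate(self):
        params = [np.zeros(3)]
        opt = Adam(params, lr=0.01)
        deltas = opt.step([np.array([1.0, -2.0, 0.5])])
        np.testing.assert_allclose(np.abs(deltas[0]), 0.01, rtol=1e-5)
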