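"""The NumPy network engine: initializer statistics, layer semantics
against brute-force tensor arithmetic, loss values, and end-to-end
gradient correctness by finite differences."""

import math

import numpy as np
import pytest

from admixer.arch import ArchitectureSpec, LayerSpec
from admixer.nn import Network, cross_entropy_loss, make_initializer, make_optimizer
from admixer.nn.initializers import TRUNC_VAR_FACTOR
from admixer.nn.losses import one_hot


class TestInitializers:
    def test_glorot_uniform_bound_is_one_at_fan_six(self, rng):
        sampler = make_initializer("glorot_uniform", 3, 3)  # sqrt(6/6) = 1
        w = sampler(rng, 10_000)
        assert np.all(np.abs(w) <= 1.0)

    def test_he_uniform_bound(self, rng):
        sampler = make_initializer("he_uniform", 6, 1)  # sqrt(6/6) = 1
        w = sampler(rng, 10_000)
        assert np.all(np.abs(w) <= 1.0)
        assert np.abs(w).max() > 0.9  # the bound is actually approached

    def test_glorot_normal_variance_truncation_corrected(self, rng):
        # n_in = n_out = 100 -> nominal variance 1/100, shrunk by the
        # +-2 std truncation factor
        sampler = make_initializer("glorot_normal", 100, 100)
        w = sampler(rng, 100_000)
        expected = TRUNC_VAR_FACTOR * (2.0 / 200.0)
        assert w.var() == pytest.approx(expected, rel=0.1)
        assert np.abs(w).max() <= 2.0 * math.sqrt(2.0 / 200.0) + 1e-12

    def test_he_normal_variance(self, rng):
        sampler = make_initializer("he_normal", 50, 10)
        w = sampler(rng, 100_000)
        assert w.var() == pytest.approx(TRUNC_VAR_FACTOR * 2.0 / 50.0, rel=0.1)

    def test_unknown_scheme_lists_options(self):
        with pytest.raises(ValueError, match="glorot_normal"):
            make_initializer("xavier", 3, 3)


def tiny_arch():
    return ArchitectureSpec(
        (12, 12, 2),
        [
            LayerSpec("conv", kernel=(3, 3), filters=2, activation="relu"),
            LayerSpec("avg_pool", kernel=(2, 2), stride=2),
            LayerSpec("separable_conv", kernel=(3, 3), filters=3, activation="relu"),
            LayerSpec("max_pool", kernel=(2, 2), stride=2),
            LayerSpec("dropout", rate=0.3),
            LayerSpec("flatten"),
            LayerSpec("dense", units=4, activation="relu"),
            LayerSpec("dense", units=3, activation="none"),
            LayerSpec("softmax"),
        ],
    )


def brute_force_conv(x, W, b):
    """Direct sliding-window correlation, one output position at a time."""
    h, w, cin = x.shape
    kh, kw, _, f = W.shape
    out = np.zeros((h - kh + 1, w - kw + 1, f))
    for a in range(out.shape[0]):
        for bcol in range(out.shape[1]):
            patch = x[a : a + kh, bcol : bcol + kw, :]
            for k in range(f):
                out[a, bcol, k] = (patch * W[:, :, :, k]).sum() + b[k]
    return out


class TestForwardSemantics:
    def test_conv_equals_sliding_window_correlation(self, rng):
        arch = ArchitectureSpec(
            (6, 6, 2), [LayerSpec("conv", kernel=(3, 3), filters=2, activation="none")]
        )
        net = Network(arch, seed=1)
        x = rng.random((1, 6, 6, 2))
        layer = net.layers[0]
        W = layer.params["W"].reshape(3, 3, 2, 2)
        got = layer.forward(x, training=False)[0]
        want = brute_force_conv(x[0], W, layer.params["b"])
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_separable_equals_depthwise_then_pointwise_loops(self, rng):
        arch = ArchitectureSpec(
            (5, 5, 2),
            [LayerSpec("separable_conv", kernel=(3, 3), filters=3, activation="none")],
        )
        net = Network(arch, seed=2)
        layer = net.layers[0]
        x = rng.random((1, 5, 5, 2))
        got = layer.forward(x, training=False)[0]
        Wd, Wp, b = layer.params["Wd"], layer.params["Wp"], layer.params["b"]
        depth = np.zeros((3, 3, 2))
        for a in range(3):
            for bcol in range(3):
                for c in range(2):
                    depth[a, bcol, c] = (x[0, a : a + 3, bcol : bcol + 3, c] * Wd[:, :, c]).sum()
        want = depth @ Wp + b
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_max_pool_dominates_avg_pool(self, rng):
        x = rng.random((2, 8, 8, 3))  # non-negative input
        spec = LayerSpec("max_pool", kernel=(2, 2), stride=2)
        from admixer.nn.layers import Pool2D

        mx = Pool2D(spec, (8, 8, 3), "max").forward(x, False)
        av = Pool2D(spec, (8, 8, 3), "avg").forward(x, False)
        assert np.all(mx >= av)

    def test_pooling_constant_map_is_identity_value(self):
        from admixer.nn.layers import Pool2D

        x = np.full((1, 4, 4, 2), 0.7)
        spec = LayerSpec("avg_pool", kernel=(2, 2), stride=2)
        for mode in ("avg", "max"):
            out = Pool2D(spec, (4, 4, 2), mode).forward(x, False)
            assert np.all(out == pytest.approx(0.7))

    def test_softmax_rows_are_probabilities(self, rng):
        net = Network(tiny_arch(), seed=0)
        p = net.forward(rng.random((5, 12, 12, 2)))
        assert p.shape == (5, 3)
        assert np.all(p >= 0) and np.all(p <= 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_output(self, rng):
        net = Network(tiny_arch(), seed=0)
        for layer in net.layers:
            for k in layer.params:
                layer.params[k][...] = 0.0
        p = net.forward(rng.random((2, 12, 12, 2)))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)

    def test_inference_deterministic_despite_dropout(self, rng):
        net = Network(tiny_arch(), seed=4)
        x = rng.random((3, 12, 12, 2))
        np.testing.assert_array_equal(net.forward(x), net.forward(x))

    def test_shape_mismatch_rejected(self, rng):
        net = Network(tiny_arch(), seed=0)
        with pytest.raises(ValueError, match="input shape"):
            net.forward(rng.random((1, 10, 10, 2)))


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        y = one_hot(np.array([0, 1]), 3)
        assert cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_prediction_is_ln5(self):
        y = one_hot(np.array([2]), 5)
        p = np.full((1, 5), 0.2)
        assert cross_entropy_loss(y, p) == pytest.approx(math.log(5), rel=1e-9)

    def test_hand_computed_batch(self):
        y = one_hot(np.array([0, 1]), 2)
        p = np.array([[0.5, 0.5], [0.75, 0.25]])
        want = (math.log(2) + math.log(4)) / 2
        assert cross_entropy_loss(y, p) == pytest.approx(want, rel=1e-9)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_entropy_loss(np.ones((2, 3)), np.ones((2, 4)))


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        net = Network(tiny_arch(), seed=3)
        x = rng.random((4, 12, 12, 2))
        y = np.array([0, 1, 2, 1])
        # disable dropout so the finite-difference loss is the trained loss
        for layer in net.layers:
            if hasattr(layer, "rate"):
                layer.rate = 0.0
        net.loss_and_backward(x, y)
        grads = net.gradients()

        def loss():
            return cross_entropy_loss(one_hot(y, 3), net.forward(x))

        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for p, g in zip(net.parameters(), grads):
            flat_idx = check_rng.choice(p.size, size=min(5, p.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-4, abs=1e-7)

    def test_zero_learning_rate_freezes_weights(self, rng):
        net = Network(tiny_arch(), seed=5)
        before = [p.copy() for p in net.parameters()]
        opt = make_optimizer("adam", lr=0.0)
        for _ in range(3):
            net.loss_and_backward(rng.random((4, 12, 12, 2)), np.array([0, 1, 2, 0]))
            opt.step(net.parameters(), net.gradients())
        for b, a in zip(before, net.parameters()):
            np.testing.assert_array_equal(b, a)


class TestOptimizers:
    @pytest.mark.parametrize(
        "name, lr", [("adam", 0.1), ("adagrad", 0.5), ("adamax", 0.1), ("nadam", 0.1)]
    )
    def test_descends_a_quadratic(self, name, lr):
        # adagrad's step decays like 1/sqrt(t), hence its larger rate
        w = np.array([5.0, -3.0])
        opt = make_optimizer(name, lr=lr)
        for _ in range(500):
            opt.step([w], [2 * w])  # d/dw ||w||^2
        assert np.linalg.norm(w) < 1.0

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="optimizer"):
            make_optimizer("sgdx")
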