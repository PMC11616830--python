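"""Numerics of the NumPy network kernel: conv/BN/pool oracles and gradients."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as sps

from pcgscreen.nn import (
    Adam,
    BatchNorm2d,
    Context,
    Conv2d,
    Dropout,
    Linear,
    MaxPool2d,
    bce_with_logits,
    make_resnet,
    sigmoid,
)

RNG = np.random.default_rng(1234)


def train_ctx(seed=0):
    return Context(training=True, rng=np.random.default_rng(seed))


class TestConv2d:
    def test_forward_matches_scipy_correlate(self):
        conv = Conv2d(2, 3, 3, stride=1, pad=1, rng=RNG, dtype=np.float64)
        x = RNG.normal(size=(1, 2, 7, 9))
        out = conv.forward(x, Context())
        expected = np.zeros_like(out)
        xp = np.pad(x[0], ((0, 0), (1, 1), (1, 1)))
        for f in range(3):
            expected[0, f] = sum(
                sps.correlate2d(xp[c], conv.weight.value[f, c], mode="valid")
                for c in range(2)
            )
        assert np.allclose(out, expected, atol=1e-10)

    def test_strided_output_shape(self):
        conv = Conv2d(1, 4, 3, stride=2, pad=1, rng=RNG)
        out = conv.forward(np.zeros((2, 1, 8, 10), dtype=np.float32), Context())
        assert out.shape == (2, 4, 4, 5)

    def test_gradient_check(self):
        conv = Conv2d(2, 2, 3, stride=2, pad=1, rng=RNG, dtype=np.float64)
        x = RNG.normal(size=(2, 2, 6, 6))
        target = RNG.normal(size=(2, 2, 3, 3))

        def loss_of():
            out = conv.forward(x, train_ctx())
            return 0.5 * np.sum((out - target) ** 2), out - target

        _, dout = loss_of()
        for p in conv.parameters():
            p.grad[...] = 0
        conv.backward(dout)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 1, 2, 2)]:
            orig = conv.weight.value[idx]
            conv.weight.value[idx] = orig + eps
            l1, _ = loss_of()
            conv.weight.value[idx] = orig - eps
            l2, _ = loss_of()
            conv.weight.value[idx] = orig
            assert conv.weight.grad[idx] == pytest.approx((l1 - l2) / (2 * eps), rel=1e-4)

    def test_input_gradient_check(self):
        conv = Conv2d(1, 2, 3, rng=RNG, dtype=np.float64)
        x = RNG.normal(size=(1, 1, 5, 5))
        target = RNG.normal(size=(1, 2, 5, 5))
        out = conv.forward(x, train_ctx())
        dx = conv.backward(out - target)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 0, 3, 2)]:
            xp = x.copy(); xp[idx] += eps
            lp = 0.5 * np.sum((conv.forward(xp, Context()) - target) ** 2)
            xm = x.copy(); xm[idx] -= eps
            lm = 0.5 * np.sum((conv.forward(xm, Context()) - target) ** 2)
            assert dx[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4)


class TestBatchNorm:
    def test_training_normalises_batch(self):
        bn = BatchNorm2d(3, dtype=np.float64)
        x = RNG.normal(loc=5.0, scale=3.0, size=(8, 3, 4, 4))
        out = bn.forward(x, train_ctx())
        assert np.allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-10)
        assert np.allclose(out.std(axis=(0, 2, 3)), 1, atol=1e-3)

    def test_eval_uses_running_stats(self):
        bn = BatchNorm2d(2, momentum=1.0, dtype=np.float64)
        x = RNG.normal(size=(16, 2, 3, 3))
        bn.forward(x, train_ctx())
        out = bn.forward(x, Context(training=False))
        # momentum 1.0 copies batch stats, so eval output matches train stats
        assert np.allclose(out.mean(axis=(0, 2, 3)), 0, atol=1e-6)

    def test_gradient_check(self):
        bn = BatchNorm2d(2, dtype=np.float64)
        x = RNG.normal(size=(4, 2, 3, 3))
        target = RNG.normal(size=x.shape)
        out = bn.forward(x, train_ctx())
        for p in bn.parameters():
            p.grad[...] = 0
        dx = bn.backward(out - target)
        eps = 1e-6
        idx = (1, 0, 2, 1)
        xp = x.copy(); xp[idx] += eps
        lp = 0.5 * np.sum((bn.forward(xp, train_ctx()) - target) ** 2)
        xm = x.copy(); xm[idx] -= eps
        lm = 0.5 * np.sum((bn.forward(xm, train_ctx()) - target) ** 2)
        assert dx[idx] == pytest.approx((lp - lm) / (2 * eps), rel=1e-3, abs=1e-8)


class TestPoolingAndDropout:
    def test_maxpool_matches_naive(self):
        pool = MaxPool2d(3, stride=2, pad=1)
        x = RNG.normal(size=(1, 1, 6, 6))
        out = pool.forward(x, Context())
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)), constant_values=-np.inf)
        for i in range(out.shape[2]):
            for j in range(out.shape[3]):
                block = xp[0, 0, 2 * i : 2 * i + 3, 2 * j : 2 * j + 3]
                assert out[0, 0, i, j] == block.max()

    def test_dropout_inactive_without_flags(self):
        d = Dropout(0.5)
        x = RNG.normal(size=(4, 4))
        assert np.array_equal(d.forward(x, Context(training=False)), x)

    def test_dropout_inverted_scaling(self):
        d = Dropout(0.25)
        x = np.ones((2000, 10))
        out = d.forward(x, Context(training=False, mc_dropout=True, rng=np.random.default_rng(0)))
        assert out.mean() == pytest.approx(1.0, abs=0.02)
        kept = out[out != 0]
        assert np.allclose(kept, 1 / 0.75)

    def test_dropout_requires_rng_when_active(self):
        with pytest.raises(ValueError):
            Dropout(0.5).forward(np.ones((2, 2)), Context(training=True, rng=None))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            Dropout(1.0)


class TestResNetConstruction:
    def test_lite_forward_shape_and_range(self):
        model = make_resnet("resnet18_lite", lite_width=4, input_pool=(4, 4), seed=0)
        x = np.random.default_rng(0).normal(size=(3, 1, 128, 398)).astype(np.float32)
        logits = model.forward(x, Context())
        assert logits.shape == (3,)
        assert np.all((sigmoid(logits) >= 0) & (sigmoid(logits) <= 1))

    def test_dropout_site_introspection(self):
        with_d = make_resnet("resnet18_lite", dropout_rate=0.2, dropout_in_blocks=True, seed=0)
        without = make_resnet("resnet18_lite", dropout_rate=0.2, dropout_in_blocks=False, seed=0)
        n_with = sum(1 for m in with_d.modules() if isinstance(m, Dropout))
        n_without = sum(1 for m in without.modules() if isinstance(m, Dropout))
        assert n_with > n_without  # in-block sites present only when enabled
        assert n_without == 1  # the head dropout remains

    def test_resnet50_constructible_with_bottlenecks(self):
        from pcgscreen.nn import Bottleneck

        model = make_resnet("resnet50", in_channels=3, input_pool=(4, 4), seed=0)
        n_bottleneck = sum(1 for m in model.modules() if isinstance(m, Bottleneck))
        assert n_bottleneck == 16  # 3 + 4 + 6 + 3
        assert model.n_parameters() > 2e7
        x = np.zeros((1, 3, 128, 398), dtype=np.float32)
        assert model.forward(x, Context()).shape == (1,)

    def test_state_dict_roundtrip(self):
        model = make_resnet("resnet18_lite", lite_width=4, seed=1)
        state = model.state_dict()
        other = make_resnet("resnet18_lite", lite_width=4, seed=2)
        other.load_state_dict(state)
        x = np.random.default_rng(3).normal(size=(2, 1, 32, 40)).astype(np.float32)
        assert np.array_equal(model.forward(x, Context()), other.forward(x, Context()))


class TestTrainingMechanics:
    def test_adam_reduces_loss_on_linear_problem(self):
        rng = np.random.default_rng(0)
        lin = Linear(5, 1, rng=rng, dtype=np.float64)
        x = rng.normal(size=(64, 5))
        w_true = rng.normal(size=5)
        y = (x @ w_true > 0).astype(float)
        opt = Adam(lin.parameters(), lr=0.05)
        losses = []
        for _ in range(60):
            logits = lin.forward(x, train_ctx())[:, 0]
            loss, dl = bce_with_logits(logits, y)
            losses.append(loss)
            opt.zero_grad()
            lin.backward(dl[:, None])
            opt.step()
        assert losses[-1] < 0.3 * losses[0]

    def test_bce_matches_reference_formula(self):
        z = np.array([-3.0, 0.0, 2.5])
        y = np.array([0.0, 1.0, 1.0])
        loss, grad = bce_with_logits(z, y)
        p = 1 / (1 + np.exp(-z))
        ref = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert loss == pytest.approx(ref)
        assert np.allclose(grad, (p - y) / 3)
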