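"""Autodiff core and layers: gradient checks against numerical differences,
attention against a brute-force oracle, convolution arithmetic."""

import numpy as np
import pytest

from scans import nn
from scans.nn.optim import FrozenParameterError


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def check_input_grad(layer_fn, x0, tol=1e-6):
    """Analytic input gradient of sum(layer(x)) vs central differences."""
    x = nn.Tensor(x0, requires_grad=True)
    out = layer_fn(x)
    out.sum().backward()

    def f(xd):
        return float(layer_fn(nn.Tensor(xd)).data.sum())

    assert np.abs(x.grad - numeric_grad(f, x0)).max() < tol


class TestGradients:
    def test_elementwise_chain(self, rng):
        x0 = rng.normal(size=(5, 4))
        check_input_grad(lambda x: ((x * 2 + 1).sigmoid() * x.tanh()).exp(), x0)

    def test_softmax_log_reduction(self, rng):
        x0 = rng.normal(size=(3, 6))
        check_input_grad(lambda x: (x.softmax(axis=-1) + 1e-9).log().mean(axis=0), x0)

    def test_matmul_broadcast_add(self, rng):
        x0 = rng.normal(size=(4, 3))
        w = nn.Tensor(rng.normal(size=(3, 2)))
        b = nn.Tensor(rng.normal(size=(2,)))
        check_input_grad(lambda x: (x @ w + b).relu(), x0)

    def test_conv1d_input_and_weight_grads(self, rng):
        layer = nn.Conv1d(3, 5, kernel=2, rng=rng)
        x0 = rng.normal(size=(2, 3, 8))
        check_input_grad(layer, x0)
        layer.zero_grad()
        x = nn.Tensor(x0)
        out = layer(x)
        out.sum().backward()
        w0 = layer.weight.data.copy()

        def f(wd):
            layer.weight.data = wd
            val = float(layer(nn.Tensor(x0)).data.sum())
            layer.weight.data = w0
            return val

        assert np.abs(layer.weight.grad - numeric_grad(f, w0)).max() < 1e-6

    def test_conv2d_and_pool_grads(self, rng):
        conv = nn.Conv2d(1, 3, kernel=(2, 2), rng=rng)
        pool = nn.MaxPool2d((2, 2))
        x0 = rng.normal(size=(2, 1, 6, 5))
        check_input_grad(lambda x: pool(conv(x)), x0)

    def test_maxpool1d_routes_gradient_to_argmax(self):
        x = nn.Tensor(np.array([[[1.0, 3.0, 2.0, 5.0]]]), requires_grad=True)
        out = nn.MaxPool1d(2)(x)
        out.sum().backward()
        assert np.array_equal(x.grad, [[[0.0, 1.0, 0.0, 1.0]]])

    def test_layernorm_grad(self, rng):
        ln = nn.LayerNorm(6)
        check_input_grad(ln, rng.normal(size=(3, 6)), tol=1e-5)

    def test_batchnorm_grad_in_training_mode(self, rng):
        bn = nn.BatchNorm(3, ndim=3)
        x0 = rng.normal(size=(4, 3, 5))

        def run(x):
            bn.running_mean[:] = 0  # keep stats fixed for the check
            bn.running_var[:] = 1
            return bn(x)

        check_input_grad(run, x0, tol=1e-5)

    def test_attention_grad(self, rng):
        attn = nn.MultiHeadAttention(8, 2, rng)
        check_input_grad(attn, rng.normal(size=(2, 4, 8)), tol=1e-5)


class TestAttentionOracle:
    def brute_force(self, x, attn):
        """Direct matrix arithmetic, one head at a time."""
        n, t, d = x.shape
        h, dk = attn.n_heads, attn.d_k
        q = x @ attn.w_q.weight.data + attn.w_q.bias.data
        k = x @ attn.w_k.weight.data + attn.w_k.bias.data
        v = x @ attn.w_v.weight.data + attn.w_v.bias.data
        heads = []
        for i in range(h):
            sl = slice(i * dk, (i + 1) * dk)
            scores = q[:, :, sl] @ k[:, :, sl].transpose(0, 2, 1) / np.sqrt(dk)
            e = np.exp(scores - scores.max(axis=-1, keepdims=True))
            a = e / e.sum(axis=-1, keepdims=True)
            heads.append(a @ v[:, :, sl])
        merged = np.concatenate(heads, axis=-1)
        return merged @ attn.w_o.weight.data + attn.w_o.bias.data

    def test_matches_brute_force_on_small_inputs(self, rng):
        for t, h in [(1, 1), (3, 1), (4, 2)]:
            attn = nn.MultiHeadAttention(6 if h == 1 else 8, h, rng)
            x = rng.normal(size=(2, t, attn.model_dim))
            got = attn(nn.Tensor(x)).data
            assert np.allclose(got, self.brute_force(x, attn), atol=1e-12)

    def test_single_token_degenerates_to_value_projection(self, rng):
        attn = nn.MultiHeadAttention(8, 2, rng)
        x = rng.normal(size=(1, 1, 8))
        got = attn(nn.Tensor(x)).data
        v = x @ attn.w_v.weight.data + attn.w_v.bias.data
        want = v @ attn.w_o.weight.data + attn.w_o.bias.data
        assert np.allclose(got, want, atol=1e-12)

    def test_attention_rows_sum_to_one(self, rng):
        attn = nn.MultiHeadAttention(8, 2, rng)
        x = nn.Tensor(rng.normal(size=(2, 5, 8)))
        q = attn._split_heads(attn.w_q(x), 2, 5)
        k = attn._split_heads(attn.w_k(x), 2, 5)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(attn.d_k))
        a = scores.softmax(axis=-1).data
        assert np.allclose(a.sum(axis=-1), 1.0)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            nn.MultiHeadAttention(10, 3, rng)


class TestConvArithmetic:
    def test_output_lengths_match_closed_form(self, rng):
        # kernel 2, stride 1: L -> L-1; pool 2: floor((L-1)/2)
        conv = nn.Conv1d(1, 1, kernel=2, rng=rng)
        pool = nn.MaxPool1d(2)
        x = nn.Tensor(rng.normal(size=(1, 1, 6)))
        c = conv(x)
        assert c.shape[-1] == 5
        assert pool(c).shape[-1] == 2

    def test_input_shorter_than_kernel_rejected(self, rng):
        conv = nn.Conv1d(1, 1, kernel=2, rng=rng)
        with pytest.raises(ValueError):
            conv(nn.Tensor(np.zeros((1, 1, 1))))

    def test_relu_definition(self):
        x = nn.Tensor(np.array([-3.0, 2.0]))
        assert np.array_equal(x.relu().data, [0.0, 2.0])

    def test_zero_input_zero_bias_conv_relu_pool_is_zero(self, rng):
        conv = nn.Conv1d(2, 3, kernel=2, rng=rng)
        conv.bias.data[:] = 0.0
        out = nn.MaxPool1d(2)(conv(nn.Tensor(np.zeros((1, 2, 8)))).relu())
        assert np.allclose(out.data, 0.0)


class TestOptimizerAndFreezing:
    def test_adam_reduces_quadratic_loss(self, rng):
        w = nn.Parameter(rng.normal(size=(5,)))
        target = np.arange(5.0)
        opt = nn.Adam([w], lr=0.05)
        first = None
        for _ in range(200):
            loss = ((w - nn.Tensor(target)) ** 2).sum()
            if first is None:
                first = float(loss.data)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert float(loss.data) < 1e-3 * first

    def test_frozen_parameter_rejected_by_optimizer(self):
        p = nn.Parameter(np.zeros(3))
        p.frozen = True
        with pytest.raises(FrozenParameterError):
            nn.Adam([p])

    def test_freeze_after_setup_raises_on_step(self):
        p = nn.Parameter(np.zeros(3))
        opt = nn.Adam([p])
        ((p * 2.0) ** 2).sum().backward()
        p.frozen = True
        with pytest.raises(FrozenParameterError):
            opt.step()


class TestStateDict:
    def test_round_trip_including_running_stats(self, rng):
        bn = nn.BatchNorm(3, ndim=3)
        bn(nn.Tensor(rng.normal(size=(4, 3, 5))))  # update running stats
        state = bn.state_dict()
        fresh = nn.BatchNorm(3, ndim=3)
        fresh.load_state_dict(state)
        assert np.array_equal(fresh.running_mean, bn.running_mean)
        assert np.array_equal(fresh.running_var, bn.running_var)

    def test_mismatched_state_rejected(self, rng):
        lin = nn.Linear(3, 2, rng)
        with pytest.raises(ValueError):
            lin.load_state_dict({"weight": np.zeros((3, 2))})
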