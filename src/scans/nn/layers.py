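"""Neural-network building blocks on top of the autodiff core.

Implements the pieces the site-prediction architecture needs: dense layers,
1-D/2-D convolutions with batch normalization and max pooling, layer
normalization, dropout, and multi-head scaled dot-product attention.
Initialization is fan-in uniform from a caller-supplied generator so whole
networks are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Parameter, Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "LayerNorm",
    "Dropout",
    "MaxPool1d",
    "MaxPool2d",
    "MultiHeadAttention",
    "Sequential",
]


class Module:
    """Minimal container with parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True
        self._buffers: list[str] = []  # non-trainable state (running stats)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def freeze(self, flag: bool = True):
        """Mark every parameter as frozen (excluded from optimizer updates)."""
        for p in self.parameters():
            p.frozen = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        *path, leaf = dotted.split(".")
        obj = self
        for part in path:  # list children are addressed as name.index
            obj = obj[int(part)] if part.isdigit() else vars(obj)[part]
        setattr(obj, leaf, np.asarray(value, dtype=np.float64).copy())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            out["buffer::" + name] = np.asarray(buf).copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buf_names = {name for name, _ in self.named_buffers()}
        expected = set(own) | {"buffer::" + b for b in buf_names}
        if expected != set(state):
            missing = expected ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            p.data = np.asarray(state[name], dtype=np.float64).reshape(p.shape).copy()
        for name in buf_names:
            self._set_buffer(name, state["buffer::" + name])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_uniform_init(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(_uniform_init(rng, (out_dim,), in_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Cross-correlation over the last axis; input (N, C_in, L)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, padding: int = 0):
        super().__init__()
        fan_in = in_ch * kernel
        self.weight = Parameter(_uniform_init(rng, (out_ch, in_ch, kernel), fan_in))
        self.bias = Parameter(_uniform_init(rng, (out_ch,), fan_in))
        self.kernel = kernel
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        w, b, k, pad = self.weight, self.bias, self.kernel, self.padding
        xd = x.data
        if pad:
            xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad)))
        if xd.shape[-1] < k:
            raise ValueError(f"input length {xd.shape[-1]} shorter than kernel {k}")
        xw = sliding_window_view(xd, k, axis=2)  # (N, C_in, L_out, k)
        out_data = np.einsum("nclk,ock->nol", xw, w.data) + b.data[None, :, None]
        l_out = out_data.shape[-1]

        def backward(g):
            if w.requires_grad:
                w._accumulate(np.einsum("nclk,nol->ock", xw, g))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gx = np.zeros_like(xd)
                for i in range(k):
                    gx[:, :, i:i + l_out] += np.einsum("nol,oc->ncl", g, w.data[:, :, i])
                if pad:
                    gx = gx[:, :, pad:-pad]
                x._accumulate(gx)

        prev = tuple(t for t in (x, w, b) if t.requires_grad)
        out = Tensor(out_data, requires_grad=bool(prev), _prev=prev)
        if prev:
            out._backward = backward
        return out


class Conv2d(Module):
    """Cross-correlation over the two trailing axes; input (N, C_in, H, W)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator, padding: int = 0):
        super().__init__()
        kh, kw = kernel
        fan_in = in_ch * kh * kw
        self.weight = Parameter(_uniform_init(rng, (out_ch, in_ch, kh, kw), fan_in))
        self.bias = Parameter(_uniform_init(rng, (out_ch,), fan_in))
        self.kernel = kernel
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        kh, kw = self.kernel
        pad = self.padding
        xd = x.data
        if pad:
            xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if xd.shape[2] < kh or xd.shape[3] < kw:
            raise ValueError("input smaller than convolution kernel")
        xw = sliding_window_view(xd, (kh, kw), axis=(2, 3))  # (N,C,H_out,W_out,kh,kw)
        out_data = (np.einsum("nchwij,ocij->nohw", xw, w.data)
                    + b.data[None, :, None, None])
        h_out, w_out = out_data.shape[2:]

        def backward(g):
            if w.requires_grad:
                w._accumulate(np.einsum("nchwij,nohw->ocij", xw, g))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gx = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, :, i:i + h_out, j:j + w_out] += np.einsum(
                            "nohw,oc->nchw", g, w.data[:, :, i, j])
                if pad:
                    gx = gx[:, :, pad:-pad, pad:-pad]
                x._accumulate(gx)

        prev = tuple(t for t in (x, w, b) if t.requires_grad)
        out = Tensor(out_data, requires_grad=bool(prev), _prev=prev)
        if prev:
            out._backward = backward
        return out


class MaxPool1d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        n, c, l = x.shape
        l_out = l // k
        if l_out == 0:
            raise ValueError(f"input length {l} shorter than pool kernel {k}")
        xr = x.data[:, :, : l_out * k].reshape(n, c, l_out, k)
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gx = np.zeros_like(x.data)
            gx[:, :, : l_out * k] = gr.reshape(n, c, l_out * k)
            x._accumulate(gx)

        prev = (x,) if x.requires_grad else ()
        out = Tensor(out_data, requires_grad=bool(prev), _prev=prev)
        if prev:
            out._backward = backward
        return out


class MaxPool2d(Module):
    def __init__(self, kernel: tuple[int, int] = (2, 2)):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        kh, kw = self.kernel
        n, c, h, w = x.shape
        h_out, w_out = h // kh, w // kw
        if h_out == 0 or w_out == 0:
            raise ValueError("input smaller than pool kernel")
        xr = (x.data[:, :, : h_out * kh, : w_out * kw]
              .reshape(n, c, h_out, kh, w_out, kw)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, h_out, w_out, kh * kw))
        idx = xr.argmax(axis=-1)
        out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gr = np.zeros_like(xr)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = (gr.reshape(n, c, h_out, w_out, kh, kw)
                  .transpose(0, 1, 2, 4, 3, 5)
                  .reshape(n, c, h_out * kh, w_out * kw))
            gx = np.zeros_like(x.data)
            gx[:, :, : h_out * kh, : w_out * kw] = gr
            x._accumulate(gx)

        prev = (x,) if x.requires_grad else ()
        out = Tensor(out_data, requires_grad=bool(prev), _prev=prev)
        if prev:
            out._backward = backward
        return out


class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1).

    Learnable scale γ and shift β; a small ε stabilizes the variance.
    Running statistics (exponential moving average) are used at evaluation
    time so inference is deterministic and batch-size independent.
    """

    def __init__(self, channels: int, ndim: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        shape = (1, channels) + (1,) * (ndim - 2)
        self.gamma = Parameter(np.ones(shape))
        self.beta = Parameter(np.zeros(shape))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(shape)
        self.running_var = np.ones(shape)
        self._axes = (0,) + tuple(range(2, ndim))
        self._buffers = ["running_mean", "running_var"]

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=self._axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=self._axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class LayerNorm(Module):
    """Normalization over the last axis, standard inside transformer layers."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return self.gamma * xhat + self.beta


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with h heads over a token sequence.

    Input (N, T, model_dim); per-head queries/keys/values of width
    model_dim/h, softmax over keys scaled by 1/sqrt(d_k), concatenated and
    linearly projected back to model_dim.
    """

    def __init__(self, model_dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if model_dim % n_heads != 0:
            raise ValueError(
                f"model_dim {model_dim} not divisible by n_heads {n_heads}")
        self.model_dim = model_dim
        self.n_heads = n_heads
        self.d_k = model_dim // n_heads
        self.w_q = Linear(model_dim, model_dim, rng)
        self.w_k = Linear(model_dim, model_dim, rng)
        self.w_v = Linear(model_dim, model_dim, rng)
        self.w_o = Linear(model_dim, model_dim, rng)

    def _split_heads(self, x: Tensor, n: int, t: int) -> Tensor:
        return x.reshape(n, t, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        n, t, _ = x.shape
        q = self._split_heads(self.w_q(x), n, t)  # (N, h, T, d_k)
        k = self._split_heads(self.w_k(x), n, t)
        v = self._split_heads(self.w_v(x), n, t)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_k))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (N, h, T, d_k)
        merged = ctx.transpose(0, 2, 1, 3).reshape(n, t, self.model_dim)
        return self.w_o(merged)


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.steps = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.steps:
            x = m(x)
        return x
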