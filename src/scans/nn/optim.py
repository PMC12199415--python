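"""First-order optimizers for the autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam", "FrozenParameterError"]


class FrozenParameterError(RuntimeError):
    """Raised when an optimizer is asked to update a frozen parameter."""


class Adam:
    """Adam with bias correction (standard defaults, lr 1e-3).

    Frozen parameters may not be handed to the optimizer: attempting to do so
    raises :class:`FrozenParameterError`, which enforces the transfer-learning
    contract that a pretrained, frozen module stays bit-identical.
    """

    def __init__(self, params, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        for p in self.params:
            if getattr(p, "frozen", False):
                raise FrozenParameterError(
                    "frozen parameter passed to optimizer; exclude it or unfreeze")
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            if getattr(p, "frozen", False):
                raise FrozenParameterError("parameter was frozen after optimizer setup")
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
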