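"""The customized three-class focal loss.

For a predicted carbonylation propensity p and a three-way label
(carbonylation l_c, nonfunctional l_n, ligand l_i — exactly one active):

    loss = −(1−p)^r · l_c · log p
           − α · p^r · l_n · log(1−p)
           − β · p^r · l_i · log(1−p)

The focusing exponent r down-weights well-classified examples (the focal
mechanism); α weights errors on nonfunctional residues (overpredictions)
and β weights errors on ligand interaction sites (cross-predictions), so a
large β explicitly penalizes calling a ligand site a carbonylation site.
With r = 0 and α = β = 1 the loss reduces to binary cross-entropy with
carbonylation as the positive class.  Propensities are clamped to
[1e-7, 1−1e-7] before the logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .nn import Tensor

__all__ = ["LossParams", "custom_loss", "custom_loss_tensor", "P_EPS"]

P_EPS = 1e-7

# label codes shared with scans.features.LABEL_INDEX
_CARB, _LIGAND, _NONFUNC = 0, 1, 2


@dataclass(frozen=True)
class LossParams:
    r: float = 2.0
    alpha: float = 1.0
    beta: float = 1.0

    def __post_init__(self):
        if self.r < 0 or self.alpha < 0 or self.beta < 0:
            raise ConfigurationError(
                f"loss parameters must be nonnegative: {self}")


def custom_loss(p, labels, params: LossParams) -> float:
    """Mean loss over a batch (numpy reference implementation).

    ``p`` are propensities in (0,1); ``labels`` are integer codes
    (0 carbonylation, 1 ligand, 2 nonfunctional).
    """
    p = np.clip(np.asarray(p, dtype=float), P_EPS, 1.0 - P_EPS)
    labels = np.asarray(labels, dtype=int)
    lc = labels == _CARB
    li = labels == _LIGAND
    ln = labels == _NONFUNC
    loss = (-((1.0 - p) ** params.r) * lc * np.log(p)
            - params.alpha * (p ** params.r) * ln * np.log1p(-p)
            - params.beta * (p ** params.r) * li * np.log1p(-p))
    return float(loss.mean())


def custom_loss_tensor(p: Tensor, labels: np.ndarray, params: LossParams) -> Tensor:
    """Differentiable batch-mean loss on the autodiff graph.

    The clamp is applied to the data (values at the boundary receive the
    clamped gradient), mirroring the numpy reference.
    """
    labels = np.asarray(labels, dtype=int)
    lc = (labels == _CARB).astype(float)
    li = (labels == _LIGAND).astype(float)
    ln = (labels == _NONFUNC).astype(float)
    np.clip(p.data, P_EPS, 1.0 - P_EPS, out=p.data)
    one_minus_p = 1.0 - p
    pos = (one_minus_p ** params.r) * Tensor(lc) * p.log() * -1.0
    neg_w = Tensor(params.alpha * ln + params.beta * li)
    neg = (p ** params.r) * neg_w * one_minus_p.log() * -1.0
    return (pos + neg).mean()


def bce_loss_tensor(p: Tensor, positive_mask: np.ndarray) -> Tensor:
    """Plain binary cross-entropy against a boolean positive mask."""
    y = np.asarray(positive_mask, dtype=float)
    np.clip(p.data, P_EPS, 1.0 - P_EPS, out=p.data)
    return (Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean() * -1.0


def l2_loss_tensor(p: Tensor, positive_mask: np.ndarray) -> Tensor:
    """Squared-error loss against a boolean positive mask (ablation variant)."""
    y = np.asarray(positive_mask, dtype=float)
    return ((p - Tensor(y)) ** 2).mean()
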