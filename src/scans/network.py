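"""The two-module attention architecture for functional-site prediction.

Both the carbonylation-sites prediction module (CSPM) and the ligand
interaction-sites prediction module (LISPM) share one design:

* a TRF block — three stacked transformer layers (multi-head self-attention,
  feed-forward expansion, layer normalization, residual connections) over
  the PSSM window, capturing long-distance, protein-level context.  The
  20-dim PSSM rows are linearly projected to ``model_dim`` and learned
  positional vectors are added;
* a CNN block — parallel two-layer 1-D (over positions, properties as
  channels) and 2-D (positions × properties) convolution stacks, each
  convolution followed by batch normalization, ReLU and max pooling
  (kernel 2, stride 1, pool 2, dropout 0.5), capturing short-distance,
  segment-level physicochemical patterns.  Both branch outputs are
  flattened and concatenated.  Pooling is skipped on an axis already
  reduced to a single element so the same stack serves every window size.

The CSPM additionally consumes a language-model embedding for the center
residue through a two-layer FCNN reducer whose output is 10-dimensional.
The fused predictor concatenates both modules' feature spaces into a
four-layer fully connected head; the final activation is a sigmoid, so
outputs are carbonylation propensities in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError

__all__ = ["NetworkConfig", "TrfBlock", "CnnBlock", "EmbeddingReducer",
           "SiteModule", "ScansNetwork"]

REDUCED_EMBEDDING_DIM = 10


@dataclass(frozen=True)
class NetworkConfig:
    window_size: int = 13
    model_dim: int = 64
    n_heads: int = 4
    n_trf_layers: int = 3
    conv_channels: tuple[int, int] = (16, 32)
    conv_kernel: int = 2
    pool_kernel: int = 2
    dropout: float = 0.5
    fusion_widths: tuple[int, int, int] = (256, 64, 16)
    reducer_hidden: int = 32
    embedding_dim: int = 32
    n_physchem: int = 10

    def __post_init__(self):
        if self.window_size % 2 == 0 or self.window_size < 5:
            raise ConfigurationError(
                f"window_size must be odd and >= 5: {self.window_size}")
        if self.model_dim % self.n_heads != 0:
            raise ConfigurationError(
                f"model_dim {self.model_dim} not divisible by "
                f"n_heads {self.n_heads}")
        if self.window_size < self.conv_kernel:
            raise ConfigurationError("window shorter than convolution kernel")


class TrfLayer(nn.Module):
    """Pre-norm transformer layer: attention and FFN with residuals."""

    def __init__(self, model_dim: int, n_heads: int, rng):
        super().__init__()
        self.attn = nn.MultiHeadAttention(model_dim, n_heads, rng)
        self.norm1 = nn.LayerNorm(model_dim)
        self.norm2 = nn.LayerNorm(model_dim)
        self.ff1 = nn.Linear(model_dim, 4 * model_dim, rng)
        self.ff2 = nn.Linear(4 * model_dim, model_dim, rng)

    def forward(self, x):
        x = x + self.attn(self.norm1(x))
        return x + self.ff2(self.ff1(self.norm2(x)).relu())


class TrfBlock(nn.Module):
    """Input projection + positional vectors + stacked transformer layers.

    Output: mean over window positions, a ``model_dim`` feature vector.
    """

    def __init__(self, config: NetworkConfig, rng):
        super().__init__()
        self.proj = nn.Linear(20, config.model_dim, rng)
        self.pos = nn.Parameter(
            rng.normal(scale=0.02, size=(config.window_size, config.model_dim)))
        self.layers = [TrfLayer(config.model_dim, config.n_heads, rng)
                       for _ in range(config.n_trf_layers)]
        self.out_dim = config.model_dim

    def forward(self, x):  # x: (N, T, 20)
        h = self.proj(x) + self.pos
        for layer in self.layers:
            h = layer(h)
        return h.mean(axis=1)  # (N, model_dim)


def _conv_out_len(length: int, kernel: int, pool: int) -> int:
    length = length - kernel + 1
    if length >= pool:
        length //= pool
    return length


class CnnBlock(nn.Module):
    """Parallel 1-D and 2-D convolution stacks over the physchem window."""

    def __init__(self, config: NetworkConfig, rng, dropout_rng):
        super().__init__()
        c1, c2 = config.conv_channels
        k, pk = config.conv_kernel, config.pool_kernel
        self.conv1d_1 = nn.Conv1d(config.n_physchem, c1, k, rng)
        self.bn1d_1 = nn.BatchNorm(c1, ndim=3)
        self.conv1d_2 = nn.Conv1d(c1, c2, k, rng)
        self.bn1d_2 = nn.BatchNorm(c2, ndim=3)
        self.conv2d_1 = nn.Conv2d(1, c1, (k, k), rng)
        self.bn2d_1 = nn.BatchNorm(c1, ndim=4)
        self.conv2d_2 = nn.Conv2d(c1, c2, (k, k), rng)
        self.bn2d_2 = nn.BatchNorm(c2, ndim=4)
        self.pool1d = nn.MaxPool1d(pk)
        self.pool2d = nn.MaxPool2d((pk, pk))
        self.drop = nn.Dropout(config.dropout, dropout_rng)
        self.pool_kernel = pk

        # convolution arithmetic, asserted against a dry run at build time
        t = config.window_size
        l1 = _conv_out_len(t, k, pk)
        l2 = _conv_out_len(l1, k, pk)
        if l2 < 1:
            raise ConfigurationError(
                f"window {t} too short for two conv+pool layers")
        h1, w1 = _conv_out_len(t, k, pk), _conv_out_len(config.n_physchem, k, pk)
        h2, w2 = _conv_out_len(h1, k, pk), _conv_out_len(w1, k, pk)
        if h2 < 1 or w2 < 1:
            raise ConfigurationError(
                f"window {t} x {config.n_physchem} too small for 2-D stack")
        self.out_dim = c2 * l2 + c2 * h2 * w2

    def _maybe_pool1d(self, x):
        return self.pool1d(x) if x.shape[-1] >= self.pool_kernel else x

    def _maybe_pool2d(self, x):
        # pool each axis independently; an axis already reduced below the
        # kernel is left alone (keeps small windows viable)
        kh = self.pool_kernel if x.shape[-2] >= self.pool_kernel else 1
        kw = self.pool_kernel if x.shape[-1] >= self.pool_kernel else 1
        if kh == 1 and kw == 1:
            return x
        return nn.MaxPool2d((kh, kw))(x)

    def forward(self, x):  # x: (N, T, 10)
        n = x.shape[0]
        x1 = x.transpose(0, 2, 1)  # (N, 10, T): properties as channels
        h1 = self._maybe_pool1d(self.bn1d_1(self.conv1d_1(x1)).relu())
        h1 = self._maybe_pool1d(self.bn1d_2(self.conv1d_2(h1)).relu())
        h1 = self.drop(h1).reshape(n, -1)

        x2 = x.reshape(n, 1, x.shape[1], x.shape[2])  # (N, 1, T, 10)
        h2 = self._maybe_pool2d(self.bn2d_1(self.conv2d_1(x2)).relu())
        h2 = self._maybe_pool2d(self.bn2d_2(self.conv2d_2(h2)).relu())
        h2 = self.drop(h2).reshape(n, -1)
        return nn.concat([h1, h2], axis=1)


class EmbeddingReducer(nn.Module):
    """Two-layer FCNN reducing a language-model embedding to 10 dimensions."""

    def __init__(self, in_dim: int, hidden: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, REDUCED_EMBEDDING_DIM, rng)
        self.out_dim = REDUCED_EMBEDDING_DIM

    def forward(self, x):  # (N, in_dim)
        return self.fc2(self.fc1(x).relu()).relu()


class SiteModule(nn.Module):
    """One prediction module: TRF block + CNN block with a linear head.

    Serves as both the LISPM (trained on ligand-vs-rest) and the empirical
    part of the CSPM.
    """

    def __init__(self, config: NetworkConfig, rng, dropout_rng):
        super().__init__()
        self.trf = TrfBlock(config, rng)
        self.cnn = CnnBlock(config, rng, dropout_rng)
        self.out_dim = self.trf.out_dim + self.cnn.out_dim
        self.head = nn.Linear(self.out_dim, 1, rng)

    def features(self, physchem, pssm):
        return nn.concat([self.trf(pssm), self.cnn(physchem)], axis=1)

    def forward(self, physchem, pssm):
        """Standalone propensity from this module alone (pretraining head)."""
        logits = self.head(self.features(physchem, pssm))
        return logits.reshape(-1).sigmoid()


class ScansNetwork(nn.Module):
    """LISPM + CSPM + embedding reducer + four-layer fusion head.

    ``forward`` takes the three feature channels as
    :class:`~scans.nn.Tensor` (or array) inputs and a mode:

    * ``"lispm"`` — the ligand module's own propensity (empirical features
      only); used during pretraining;
    * ``"cspm"`` — the carbonylation module plus reduced embedding through
      its own head; no ligand knowledge;
    * ``"fused"`` — both modules' feature spaces concatenated into the
      four-layer FCNN head (the full predictor).
    """

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
        self.dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 72]))
        self.lispm = SiteModule(config, rng, self.dropout_rng)
        self.cspm = SiteModule(config, rng, self.dropout_rng)
        self.reducer = EmbeddingReducer(config.embedding_dim,
                                        config.reducer_hidden, rng)
        cspm_full = self.cspm.out_dim + self.reducer.out_dim
        self.cspm_head = nn.Linear(cspm_full, 1, rng)
        w1, w2, w3 = config.fusion_widths
        fused_in = cspm_full + self.lispm.out_dim
        self.fusion = [
            nn.Linear(fused_in, w1, rng),
            nn.Linear(w1, w2, rng),
            nn.Linear(w2, w3, rng),
            nn.Linear(w3, 1, rng),
        ]
        # dry run asserts the convolution arithmetic
        t, p = config.window_size, config.n_physchem
        probe = self.cspm.cnn(nn.Tensor(np.zeros((1, t, p))))
        assert probe.shape == (1, self.cspm.cnn.out_dim), (
            probe.shape, self.cspm.cnn.out_dim)

    @staticmethod
    def _lift(x) -> nn.Tensor:
        return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, dtype=float))

    def forward(self, physchem, pssm, embedding=None, mode: str = "fused"):
        physchem = self._lift(physchem)
        pssm = self._lift(pssm)
        if mode == "lispm":
            return self.lispm(physchem, pssm)
        if embedding is None:
            embedding = nn.Tensor(np.zeros((physchem.shape[0],
                                            self.config.embedding_dim)))
        embedding = self._lift(embedding)
        cspm_feat = nn.concat(
            [self.cspm.features(physchem, pssm), self.reducer(embedding)], axis=1)
        if mode == "cspm":
            return self.cspm_head(cspm_feat).reshape(-1).sigmoid()
        if mode != "fused":
            raise ConfigurationError(f"unknown forward mode {mode!r}")
        lispm_feat = self.lispm.features(physchem, pssm)
        h = nn.concat([cspm_feat, lispm_feat], axis=1)
        for layer in self.fusion[:-1]:
            h = layer(h).relu()
        return self.fusion[-1](h).reshape(-1).sigmoid()

    def predict_proba(self, physchem, pssm, embedding=None,
                      mode: str = "fused") -> np.ndarray:
        """Deterministic inference (dropout off, batch-norm running stats)."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(physchem, pssm, embedding, mode=mode)
        finally:
            self.train(was_training)
        return out.data
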