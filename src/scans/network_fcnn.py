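"""Ablation variant: attention blocks replaced by plain dense networks.

Keeps the two-module structure (ligand module, carbonylation module with
embedding reducer, fusion head) and the same forward modes as the full
network, but each module is a two-layer FCNN over the flattened
physicochemical and PSSM windows instead of the CNN/TRF attention blocks.
Used to measure what the attention mechanisms contribute.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .errors import ConfigurationError
from .network import EmbeddingReducer, NetworkConfig

__all__ = ["FcnnNetwork"]


class FcnnSiteModule(nn.Module):
    def __init__(self, config: NetworkConfig, rng):
        super().__init__()
        in_dim = config.window_size * (config.n_physchem + 20)
        hidden = config.model_dim * 2
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, config.model_dim, rng)
        self.out_dim = config.model_dim
        self.head = nn.Linear(self.out_dim, 1, rng)

    def features(self, physchem, pssm):
        n = physchem.shape[0]
        flat = nn.concat([physchem.reshape(n, -1), pssm.reshape(n, -1)], axis=1)
        return self.fc2(self.fc1(flat).relu()).relu()

    def forward(self, physchem, pssm):
        return self.head(self.features(physchem, pssm)).reshape(-1).sigmoid()


class FcnnNetwork(nn.Module):
    """Same contract as the attention network; dense modules throughout."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
        self.lispm = FcnnSiteModule(config, rng)
        self.cspm = FcnnSiteModule(config, rng)
        self.reducer = EmbeddingReducer(config.embedding_dim,
                                        config.reducer_hidden, rng)
        cspm_full = self.cspm.out_dim + self.reducer.out_dim
        self.cspm_head = nn.Linear(cspm_full, 1, rng)
        w1, w2, w3 = config.fusion_widths
        self.fusion = [
            nn.Linear(cspm_full + self.lispm.out_dim, w1, rng),
            nn.Linear(w1, w2, rng),
            nn.Linear(w2, w3, rng),
            nn.Linear(w3, 1, rng),
        ]

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
        h = nn.concat([cspm_feat, self.lispm.features(physchem, pssm)], axis=1)
        for layer in self.fusion[:-1]:
            h = layer(h).relu()
        return self.fusion[-1](h).reshape(-1).sigmoid()

    def predict_proba(self, physchem, pssm, embedding=None,
                      mode: str = "fused") -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            out = self.forward(physchem, pssm, embedding, mode=mode)
        finally:
            self.train(was_training)
        return out.data
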