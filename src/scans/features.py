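"""Feature channels for segments: physicochemical, PSSM window, embeddings.

Three channels feed the predictor:

* a (2w+1)×10 binary physicochemical matrix per segment, from ten residue
  properties (hydrophilicity, hydrophobicity, tiny, acidity, positive /
  negative charge, polarity, aromaticity, sulfur content, aliphatic); the
  residue-to-property table ships as an editable TSV with the package, and
  the padding character 'X' maps to the zero vector;
* a (2w+1)×20 window sliced from the protein-level PSSM log-odds profile,
  with terminal overhang filled by the uniform-background row (all zeros in
  log-odds space);
* one embedding vector for the center residue from a pluggable provider.
  The built-in providers are a zero provider (the network runs without a
  language model) and a synthetic 3-mer-projection provider; a real
  language-model provider can be adapted to the same contract.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .data import AMINO_ACIDS, PAD_CHAR, TARGET_RESIDUES, Label, Segment, crop_window
from .errors import ConfigurationError, ConsistencyError, DataError

__all__ = [
    "load_physchem_table",
    "encode_physchem",
    "read_pssm_tsv",
    "encode_pssm_window",
    "background_pssm_row",
    "reduce_embedding",
    "EmbeddingProvider",
    "NullEmbeddingProvider",
    "SyntheticEmbeddingProvider",
    "FeatureBundle",
    "SegmentFeaturizer",
    "LABEL_INDEX",
]

N_PHYSCHEM = 10
#: Integer codes used throughout training: 0 carbonylation, 1 ligand, 2 nonfunctional.
LABEL_INDEX = {Label.CARBONYLATION: 0, Label.LIGAND: 1, Label.NONFUNCTIONAL: 2}

_physchem_cache: dict[str, np.ndarray] | None = None


def load_physchem_table(path=None) -> dict[str, np.ndarray]:
    """Residue → 10-vector of binary property indicators.

    Reads the packaged table by default; a custom table with the same layout
    may be supplied.  'X' (terminal padding) maps to the zero vector.
    """
    global _physchem_cache
    if path is None:
        if _physchem_cache is not None:
            return _physchem_cache
        source = resources.files("scans").joinpath("data_tables/physchem.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if len(header) != N_PHYSCHEM + 1:
        raise DataError(
            f"physicochemical table must have {N_PHYSCHEM} property columns")
    table: dict[str, np.ndarray] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        table[parts[0]] = np.array([float(v) for v in parts[1:]])
    missing = set(AMINO_ACIDS) - set(table)
    if missing:
        raise DataError(f"physicochemical table missing residues {sorted(missing)}")
    table[PAD_CHAR] = np.zeros(N_PHYSCHEM)
    if path is None:
        _physchem_cache = table
    return table


def encode_physchem(segment: Segment | str, table=None) -> np.ndarray:
    """(2w+1)×10 binary matrix; row i encodes window character i."""
    window = segment.window if isinstance(segment, Segment) else segment
    table = table or load_physchem_table()
    rows = []
    for c in window:
        if c not in table:
            raise DataError(f"cannot encode unknown residue character {c!r}")
        rows.append(table[c])
    return np.array(rows)


# ---------------------------------------------------------------------------
# PSSM window


def background_pssm_row() -> np.ndarray:
    """Uniform-background log-odds row (identically zero)."""
    return np.zeros(20)


def read_pssm_tsv(path, column_order: str = AMINO_ACIDS) -> np.ndarray:
    """Read an L×20 PSSM matrix from TSV, reordering columns to ACDE...Y.

    Tolerates an optional single header line of residue letters; only the
    20-column matrix portion of common PSSM dialects is interpreted.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    start = 0
    first = lines[0].split("\t")
    if any(not _is_number(tok) for tok in first):
        header = [tok.strip() for tok in first]
        if len(header) == 20 and all(h in AMINO_ACIDS for h in header):
            column_order = "".join(header)
        start = 1
    rows = []
    for ln in lines[start:]:
        vals = [float(v) for v in ln.split("\t")]
        if len(vals) != 20:
            raise DataError(f"PSSM row has {len(vals)} columns, expected 20")
        rows.append(vals)
    mat = np.array(rows)
    if column_order != AMINO_ACIDS:
        if sorted(column_order) != sorted(AMINO_ACIDS):
            raise ConfigurationError(f"bad PSSM column order {column_order!r}")
        perm = [column_order.index(aa) for aa in AMINO_ACIDS]
        mat = mat[:, perm]
    return mat


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def encode_pssm_window(pssm_profile: np.ndarray, center_pos: int,
                       window_size: int) -> np.ndarray:
    """window_size×20 slice of the profile centered at ``center_pos`` (1-based).

    Rows that fall outside the protein (terminal overhang) are filled with
    the uniform-background row.
    """
    if window_size % 2 == 0:
        raise ConfigurationError(f"window_size must be odd, got {window_size}")
    L = pssm_profile.shape[0]
    if not 1 <= center_pos <= L:
        raise ConsistencyError(
            f"center position {center_pos} outside profile of length {L}")
    w = window_size // 2
    c = center_pos - 1
    out = np.tile(background_pssm_row(), (window_size, 1))
    lo, hi = max(0, c - w), min(L, c + w + 1)
    out[lo - (c - w):lo - (c - w) + (hi - lo)] = pssm_profile[lo:hi]
    return out


# ---------------------------------------------------------------------------
# Embedding providers


class EmbeddingProvider:
    """Contract: ``provider(sequence)`` returns one ``dim``-vector per residue."""

    name: str = "abstract"
    dim: int = 0

    def __call__(self, sequence: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class NullEmbeddingProvider(EmbeddingProvider):
    """All-zero embeddings; lets the predictor run without a language model."""

    name = "null"

    def __init__(self, dim: int = 32):
        self.dim = dim

    def __call__(self, sequence: str) -> np.ndarray:
        return np.zeros((len(sequence), self.dim))


class SyntheticEmbeddingProvider(EmbeddingProvider):
    """Embeddings from the synthetic 3-mer projection (see :mod:`scans.simulate`)."""

    name = "synthetic"

    def __init__(self, dim: int = 32, seed: int = 0, noise: float = 0.0):
        from .simulate import SimulationConfig  # deferred: avoid cycle at import
        self.dim = dim
        self._config = SimulationConfig(embedding_dim=dim, seed=seed,
                                        embedding_noise=noise)

    def __call__(self, sequence: str) -> np.ndarray:
        from .data import AnnotatedProtein
        from .simulate import simulate_embeddings
        labels = [Label.NONFUNCTIONAL if aa in TARGET_RESIDUES else Label.NOT_TARGET
                  for aa in sequence]
        pseudo = AnnotatedProtein(f"Q{zlib.crc32(sequence.encode()):08x}",
                                  sequence, labels)
        return simulate_embeddings(pseudo, self._config)


def reduce_embedding(raw_vector: np.ndarray, reducer_params: dict,
                     activation: str = "relu") -> np.ndarray:
    """Apply a two-layer affine reducer; output has exactly 10 components.

    ``reducer_params`` holds ``w1`` (dim×h), ``b1``, ``w2`` (h×10), ``b2``.
    This is the functional form of the trainable reducer inside the network;
    it applies the parameters it is given.
    """
    w1, b1, w2, b2 = (np.asarray(reducer_params[k]) for k in ("w1", "b1", "w2", "b2"))
    if raw_vector.shape[-1] != w1.shape[0]:
        raise ConfigurationError(
            f"embedding dim {raw_vector.shape[-1]} != reducer input {w1.shape[0]}")
    if w2.shape[1] != 10:
        raise ConfigurationError("reducer output dimension must be 10")
    h = raw_vector @ w1 + b1
    if activation == "relu":
        h = np.maximum(h, 0.0)
    elif activation != "linear":
        raise ConfigurationError(f"unknown activation {activation!r}")
    out = h @ w2 + b2
    if activation == "relu":
        out = np.maximum(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# Bundling


@dataclass
class FeatureBundle:
    """All three channels for one segment, plus its label."""

    physchem: np.ndarray       # (2w+1) x 10
    pssm_window: np.ndarray    # (2w+1) x 20
    embedding: np.ndarray      # (provider dim,) center-residue vector
    label: Label

    def __post_init__(self):
        if self.physchem.shape[0] != self.pssm_window.shape[0]:
            raise ConsistencyError("channel window sizes disagree")


class SegmentFeaturizer:
    """Transformer turning stored segments into stacked feature arrays.

    Parameters
    ----------
    window_size : odd int
        Working window; stored segments (typically 27 long) are cropped to
        this size for the physicochemical channel, and the PSSM window uses
        the same size.
    embedding_provider : EmbeddingProvider
        Source of per-residue embeddings; only the center residue's vector
        enters the bundle.
    """

    def __init__(self, window_size: int = 27,
                 embedding_provider: EmbeddingProvider | None = None):
        if window_size % 2 == 0:
            raise ConfigurationError(f"window_size must be odd, got {window_size}")
        self.window_size = window_size
        self.embedding_provider = embedding_provider or NullEmbeddingProvider()

    def get_params(self, deep: bool = True) -> dict:
        return {"window_size": self.window_size,
                "embedding_provider": self.embedding_provider}

    def set_params(self, **params) -> "SegmentFeaturizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def bundle(self, segment: Segment, pssm_profile: np.ndarray,
               embedding: np.ndarray | None = None) -> FeatureBundle:
        seg = crop_window(segment, self.window_size)
        if embedding is None:
            embedding = np.zeros(self.embedding_provider.dim)
        return FeatureBundle(
            physchem=encode_physchem(seg),
            pssm_window=encode_pssm_window(pssm_profile, segment.center_pos,
                                           self.window_size),
            embedding=embedding,
            label=segment.label,
        )

    def transform(self, segments, pssms: dict[str, np.ndarray],
                  sequences: dict[str, str] | None = None) -> dict[str, np.ndarray]:
        """Stack features for many segments.

        ``pssms`` maps protein id → L×20 profile.  ``sequences`` (protein id
        → sequence) is needed when the provider is non-null; embeddings are
        computed per protein once and the center-residue rows gathered.
        """
        segments = list(segments)
        emb_cache: dict[str, np.ndarray] = {}
        phys, pssm_w, embs, labels = [], [], [], []
        for seg in segments:
            if seg.protein_id not in pssms:
                raise DataError(f"no PSSM profile for protein {seg.protein_id!r}")
            profile = pssms[seg.protein_id]
            if isinstance(self.embedding_provider, NullEmbeddingProvider) or sequences is None:
                emb = np.zeros(self.embedding_provider.dim)
            else:
                if seg.protein_id not in emb_cache:
                    emb_cache[seg.protein_id] = self.embedding_provider(
                        sequences[seg.protein_id])
                emb = emb_cache[seg.protein_id][seg.center_pos - 1]
            b = self.bundle(seg, profile, emb)
            phys.append(b.physchem)
            pssm_w.append(b.pssm_window)
            embs.append(b.embedding)
            labels.append(LABEL_INDEX[seg.label])
        return {
            "physchem": np.array(phys),
            "pssm": np.array(pssm_w),
            "embedding": np.array(embs),
            "labels": np.array(labels, dtype=int),
        }
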