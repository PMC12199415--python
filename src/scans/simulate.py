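"""Seeded generator of annotated proteins, PSSM profiles and embeddings.

The generator emulates the statistical structure the predictor assumes:

* K/P/R/T target residues labeled carbonylation / ligand / nonfunctional at
  roughly 2% / 6% / 92%, the class imbalance typical of curated
  carbonylation benchmarks;
* carbonylation sites whose neighborhoods are enriched for short planted
  sequence motifs;
* ligand interaction sites with a distinct compositional bias (elevated
  aromatic content) plus a shared slice of the motif vocabulary at lower
  frequency, so the two positive classes are separable but confusable —
  cross-prediction is observable by construction;
* PSSM profiles that are sharpened one-hot rows mixed with background and
  log-odds transformed, with optional Gaussian noise;
* per-residue embeddings from a fixed random projection of the local 3-mer,
  standing in for a protein language model.

All randomness flows from ``SimulationConfig.seed`` through named
sub-streams (proteins / PSSM / embeddings, then per-protein), so any subset
of the outputs is reproducible independently of generation order.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import (
    AMINO_ACIDS,
    TARGET_RESIDUES,
    AnnotatedProtein,
    Label,
    write_annotations,
)
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "simulate_proteins",
    "simulate_pssm",
    "simulate_embeddings",
    "write_dataset",
]

_AROMATIC = "FWYH"
# Sub-stream tags for the hierarchical seed split.
_STREAM_PROTEINS, _STREAM_PSSM, _STREAM_EMBED = 1, 2, 3


@dataclass(frozen=True)
class SimulationConfig:
    n_proteins: int = 100
    length_range: tuple[int, int] = (80, 300)
    class_props: tuple[float, float, float] = (0.02, 0.06, 0.92)
    planted_motifs: tuple[str, ...] = ("LQSGE", "ENFDA", "CSLxA")
    plant_prob: float = 0.5
    plant_span: int = 6
    shared_motif_prob: float = 0.15
    aromatic_bias: int = 3
    pssm_sharpness: float = 0.8
    pssm_noise: float = 0.3
    embedding_dim: int = 32
    embedding_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        p = self.class_props
        if len(p) != 3 or any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_props must be 3 nonnegative values summing to 1: {p}")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ConfigurationError(f"plant_prob must be in [0,1]: {self.plant_prob}")
        if self.plant_prob > 0 and not self.planted_motifs:
            raise ConfigurationError(
                "nonzero plant_prob requires a nonempty motif list")
        if not 0.0 < self.pssm_sharpness <= 1.0 and self.pssm_sharpness != 0.0:
            raise ConfigurationError(
                f"pssm_sharpness must be in [0,1]: {self.pssm_sharpness}")
        if self.pssm_noise < 0 or self.embedding_noise < 0:
            raise ConfigurationError("noise scales must be nonnegative")
        if self.embedding_dim < 1:
            raise ConfigurationError("embedding_dim must be >= 1")
        if self.length_range[0] < 20 or self.length_range[0] > self.length_range[1]:
            raise ConfigurationError(f"bad length_range {self.length_range}")


def _stream(seed: int, tag: int, key: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, tag, key]))


def _protein_key(protein_id: str) -> int:
    return zlib.crc32(protein_id.encode())


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(list(AMINO_ACIDS)) if c == "x" else c for c in pattern)


def _plant(seq: list[str], center: int, motif: str, span: int,
           blocked: set[int], rng: np.random.Generator) -> range | None:
    """Write ``motif`` with its start within ``span`` of ``center``, without
    touching blocked positions; returns the occupied range, or None."""
    n, m = len(seq), len(motif)
    starts = [s for s in range(max(0, center - span), min(n - m, center + span) + 1)
              if not any(s <= p < s + m for p in blocked)]
    if not starts:
        return None
    s = int(rng.choice(starts))
    seq[s:s + m] = list(motif)
    return range(s, s + m)


def simulate_proteins(config: SimulationConfig) -> list[AnnotatedProtein]:
    """Generate annotated proteins with the configured class structure.

    Site classes are assigned to the base sequence's target residues by a
    multinomial draw; motifs and compositional bias are then written into
    the flanks without overwriting any assigned site.  Labels are finalized
    on the edited sequence, so invariants (every K/P/R/T labeled, labels
    match residues) hold exactly; edits perturb only the nonfunctional pool.
    """
    p_carb, p_lig, p_non = config.class_props
    proteins = []
    for idx in range(config.n_proteins):
        pid = f"SYN{idx:05d}"
        rng = _stream(config.seed, _STREAM_PROTEINS, _protein_key(pid))
        length = int(rng.integers(config.length_range[0],
                                  config.length_range[1] + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        targets = [i for i, aa in enumerate(seq) if aa in TARGET_RESIDUES]
        draws = rng.choice(3, size=len(targets), p=[p_carb, p_lig, p_non])
        carb_pos = [t for t, d in zip(targets, draws) if d == 0]
        lig_pos = [t for t, d in zip(targets, draws) if d == 1]
        protected = set(carb_pos) | set(lig_pos)
        occupied: set[int] = set()  # planted footprints, shielded from edits

        for pos in carb_pos:
            if rng.random() < config.plant_prob:
                motif = _instantiate(
                    config.planted_motifs[rng.integers(len(config.planted_motifs))],
                    rng)
                span = _plant(seq, pos, motif, config.plant_span,
                              protected | occupied, rng)
                if span is None:
                    # neighbors blocked every placement; planting carries the
                    # carbonylation signal, so yield only to this center (a
                    # displaced neighbor reverts to background)
                    span = _plant(seq, pos, motif, config.plant_span,
                                  {pos}, rng)
                if span is not None:
                    occupied.update(span)
        for pos in lig_pos:
            # compositional bias: aromatic residues in the flank
            flank = [j for j in range(max(0, pos - 5), min(length, pos + 6))
                     if j not in protected and j not in occupied
                     and seq[j] not in TARGET_RESIDUES]
            rng.shuffle(flank)
            for j in flank[:config.aromatic_bias]:
                seq[j] = _AROMATIC[rng.integers(len(_AROMATIC))]
            # confusable vocabulary: occasionally share a carbonylation motif
            if config.planted_motifs and rng.random() < config.shared_motif_prob:
                motif = _instantiate(
                    config.planted_motifs[rng.integers(len(config.planted_motifs))],
                    rng)
                span = _plant(seq, pos, motif, config.plant_span,
                              protected | occupied, rng)
                if span is not None:
                    occupied.update(span)

        sequence = "".join(seq)
        labels = []
        for i, aa in enumerate(sequence):
            if aa not in TARGET_RESIDUES:
                labels.append(Label.NOT_TARGET)
            elif i in carb_pos:
                labels.append(Label.CARBONYLATION)
            elif i in lig_pos:
                labels.append(Label.LIGAND)
            else:
                labels.append(Label.NONFUNCTIONAL)
        proteins.append(AnnotatedProtein(pid, sequence, labels))
    return proteins


_BACKGROUND = np.full(20, 1.0 / 20)


def simulate_pssm(protein: AnnotatedProtein, config: SimulationConfig) -> np.ndarray:
    """L×20 log-odds profile: sharpened one-hot vs uniform background.

    Each row mixes a one-hot of the true residue (weight ``pssm_sharpness``)
    with the uniform background, is floored and renormalized, log2-odds
    transformed against the background, and perturbed with Gaussian noise of
    scale ``pssm_noise``.  Columns are ordered alphabetically (ACDE...Y).
    """
    rng = _stream(config.seed, _STREAM_PSSM, _protein_key(protein.id))
    L = len(protein.sequence)
    onehot = np.zeros((L, 20))
    for i, aa in enumerate(protein.sequence):
        j = AMINO_ACIDS.find(aa)
        if j >= 0:
            onehot[i, j] = 1.0
    s = config.pssm_sharpness
    probs = s * onehot + (1.0 - s) * _BACKGROUND
    probs = np.clip(probs, 1e-4, None)
    probs /= probs.sum(axis=1, keepdims=True)
    logodds = np.log2(probs / _BACKGROUND)
    if config.pssm_noise > 0:
        logodds = logodds + rng.normal(scale=config.pssm_noise, size=logodds.shape)
    return logodds


def simulate_embeddings(protein: AnnotatedProtein,
                        config: SimulationConfig) -> np.ndarray:
    """L×dim embeddings: fixed random projection of the local 3-mer one-hot.

    The projection matrix depends only on the top-level seed, so identical
    3-mers map to identical vectors across proteins (up to the additive
    smoothed positional noise).
    """
    proj_rng = _stream(config.seed, _STREAM_EMBED, 0)
    proj = proj_rng.normal(size=(3 * 21, config.embedding_dim)) / np.sqrt(3 * 21)
    alphabet = AMINO_ACIDS + "X"
    L = len(protein.sequence)
    padded = "X" + protein.sequence + "X"
    feats = np.zeros((L, 3 * 21))
    for i in range(L):
        for k in range(3):
            feats[i, k * 21 + alphabet.find(padded[i + k])] = 1.0
    emb = feats @ proj
    if config.embedding_noise > 0:
        rng = _stream(config.seed, _STREAM_EMBED, _protein_key(protein.id))
        noise = rng.normal(scale=config.embedding_noise,
                           size=(L + 2, config.embedding_dim))
        smooth = 0.25 * noise[:-2] + 0.5 * noise[1:-1] + 0.25 * noise[2:]
        emb = emb + smooth
    return emb


def write_dataset(config: SimulationConfig, outdir) -> dict:
    """Generate and write FASTA + annotations + PSSMs + embeddings + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    proteins = simulate_proteins(config)
    write_annotations(proteins, outdir / "proteins.fasta",
                      outdir / "annotations.tsv")
    pssm_dir = outdir / "pssm"
    emb_dir = outdir / "embeddings"
    pssm_dir.mkdir(exist_ok=True)
    emb_dir.mkdir(exist_ok=True)
    for p in proteins:
        np.savetxt(pssm_dir / f"{p.id}.tsv", simulate_pssm(p, config),
                   delimiter="\t", fmt="%.5f", header="\t".join(AMINO_ACIDS),
                   comments="")
        np.savetxt(emb_dir / f"{p.id}.tsv", simulate_embeddings(p, config),
                   delimiter="\t", fmt="%.5f")
    manifest = {
        "config": dataclasses.asdict(config),
        "n_proteins": len(proteins),
        "files": {
            "fasta": "proteins.fasta",
            "annotations": "annotations.tsv",
            "pssm_dir": "pssm",
            "embedding_dir": "embeddings",
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
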