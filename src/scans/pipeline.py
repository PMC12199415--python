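"""End-to-end helpers tying data, features and models together.

These functions are the programmatic equivalents of the command-line
workflows: load a dataset directory (FASTA + annotation TSV + per-protein
PSSM/embedding TSVs), extract and featurize segments for one residue type,
and run train/predict/evaluate round trips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import (
    DEFAULT_SEGMENT_LENGTH,
    AnnotatedProtein,
    Segment,
    extract_segments,
    read_annotations,
)
from .errors import DataError
from .features import SegmentFeaturizer, read_pssm_tsv
from .simulate import SimulationConfig, simulate_pssm, simulate_proteins, simulate_embeddings

__all__ = ["load_dataset", "featurize", "synthetic_feature_set"]


def load_dataset(directory) -> tuple[list[AnnotatedProtein], dict, dict]:
    """Read a dataset directory written by ``write_dataset`` (or equivalent).

    Returns (proteins, pssms, embeddings); the latter two map protein id to
    an L×20 / L×d matrix.  Missing PSSM or embedding directories yield
    empty dicts.
    """
    directory = Path(directory)
    proteins = read_annotations(directory / "proteins.fasta",
                                directory / "annotations.tsv")
    pssms, embeddings = {}, {}
    if (directory / "pssm").is_dir():
        for p in proteins:
            path = directory / "pssm" / f"{p.id}.tsv"
            if path.exists():
                pssms[p.id] = read_pssm_tsv(path)
    if (directory / "embeddings").is_dir():
        for p in proteins:
            path = directory / "embeddings" / f"{p.id}.tsv"
            if path.exists():
                embeddings[p.id] = np.loadtxt(path, delimiter="\t", ndmin=2)
    return proteins, pssms, embeddings


def featurize(proteins: list[AnnotatedProtein], pssms: dict, residue_type: str,
              window_size: int, embeddings: dict | None = None,
              segment_length: int = DEFAULT_SEGMENT_LENGTH,
              ) -> tuple[list[Segment], dict, np.ndarray]:
    """Extract segments for one residue type and stack the feature channels.

    Stored segments are ``segment_length`` (27) wide; channels are cropped
    to ``window_size``.  Embedding vectors, when provided, are the center
    residue's row of the per-protein matrix; otherwise zeros.
    """
    segments: list[Segment] = []
    for p in proteins:
        if p.id not in pssms:
            raise DataError(f"no PSSM profile for protein {p.id!r}")
        segments.extend(extract_segments(p, residue_type, segment_length))
    feat = SegmentFeaturizer(window_size=window_size)
    X = feat.transform(segments, pssms)
    if embeddings:
        emb_dim = next(iter(embeddings.values())).shape[1]
        rows = np.zeros((len(segments), emb_dim))
        for i, seg in enumerate(segments):
            mat = embeddings.get(seg.protein_id)
            if mat is not None:
                rows[i] = mat[seg.center_pos - 1]
        X["embedding"] = rows
    y = X.pop("labels")
    return segments, X, y


def synthetic_feature_set(config: SimulationConfig, residue_type: str,
                          window_size: int, use_embeddings: bool = True,
                          ) -> tuple[list[Segment], dict, np.ndarray]:
    """Generate a synthetic dataset in memory and featurize it directly."""
    proteins = simulate_proteins(config)
    pssms = {p.id: simulate_pssm(p, config) for p in proteins}
    embeddings = ({p.id: simulate_embeddings(p, config) for p in proteins}
                  if use_embeddings else None)
    return featurize(proteins, pssms, residue_type, window_size,
                     embeddings=embeddings)
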