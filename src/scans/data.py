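"""Domain types and segment extraction for carbonylation-site prediction.

A protein is annotated per residue with one of three functional labels on
the four target residue types lysine (K), proline (P), arginine (R) and
threonine (T): ``carbonylation``, ``ligand`` (ligand interaction site) or
``nonfunctional``.  All other residues are ``not_target`` and never enter
the prediction problem.  The unit of prediction is a fixed odd-length
window (segment) centered on a target residue, padded at the sequence
termini with 'X'.

Annotation positions are 1-based inclusive, matching the convention of
post-translational-modification databases; everything internal is 0-based.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigurationError, ConsistencyError, DataError

__all__ = [
    "Label",
    "TARGET_RESIDUES",
    "AMINO_ACIDS",
    "PAD_CHAR",
    "AnnotatedProtein",
    "Segment",
    "DatasetSplit",
    "read_annotations",
    "write_annotations",
    "extract_segments",
    "crop_window",
    "split_dataset",
    "segments_to_tsv",
    "segments_from_tsv",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
TARGET_RESIDUES = "KPRT"
PAD_CHAR = "X"
#: Default stored segment length; models crop to their working window.
DEFAULT_SEGMENT_LENGTH = 27
#: Optimized working window per residue type (K, P, R, T).
DEFAULT_WINDOW_SIZES = {"K": 13, "P": 15, "R": 17, "T": 17}


class Label(str, Enum):
    CARBONYLATION = "carbonylation"
    LIGAND = "ligand"
    NONFUNCTIONAL = "nonfunctional"
    NOT_TARGET = "not_target"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


#: The three labels a target residue (and hence a segment) may carry.
SEGMENT_LABELS = (Label.CARBONYLATION, Label.LIGAND, Label.NONFUNCTIONAL)


@dataclass
class AnnotatedProtein:
    """A sequence with one functional label per residue."""

    id: str
    sequence: str
    labels: list[Label]

    def __post_init__(self):
        if len(self.labels) != len(self.sequence):
            raise ConsistencyError(
                f"{self.id}: {len(self.labels)} labels for "
                f"{len(self.sequence)} residues")
        for i, (aa, lab) in enumerate(zip(self.sequence, self.labels)):
            if aa not in TARGET_RESIDUES and lab != Label.NOT_TARGET:
                raise ConsistencyError(
                    f"{self.id} position {i + 1}: residue {aa} is not a "
                    f"target residue but carries label {lab}")

    def target_positions(self, residue_type: str) -> list[int]:
        """0-based positions of ``residue_type`` in the sequence."""
        return [i for i, aa in enumerate(self.sequence) if aa == residue_type]


@dataclass(frozen=True)
class Segment:
    """An odd-length window centered on a target residue."""

    protein_id: str
    center_pos: int  # 1-based position of the center residue
    residue_type: str
    window: str
    label: Label
    pad_count: int = 0

    def __post_init__(self):
        if len(self.window) % 2 == 0:
            raise ConfigurationError(
                f"segment window length {len(self.window)} is even")
        mid = len(self.window) // 2
        if self.window[mid] != self.residue_type:
            raise ConsistencyError(
                f"{self.protein_id}@{self.center_pos}: window center "
                f"{self.window[mid]!r} != residue type {self.residue_type!r}")


@dataclass
class DatasetSplit:
    train: list[Segment]
    validation: list[Segment]
    test: list[Segment] = field(default_factory=list)
    seed: int = 0

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


# ---------------------------------------------------------------------------
# Annotation I/O

ANNOTATION_HEADER = ["protein_id", "position", "residue", "label"]


def _read_fasta(source) -> dict[str, str]:
    if isinstance(source, (str, Path)):
        handle = open(source)
        close = True
    else:
        handle, close = source, False
    try:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()
    return seqs


def read_annotations(fasta_source, annotation_source) -> list[AnnotatedProtein]:
    """Read FASTA sequences plus a per-residue annotation table.

    The annotation table is tab-separated with header
    ``protein_id  position  residue  label``; positions are 1-based.  Every
    K/P/R/T residue without an annotation row defaults to ``nonfunctional``
    (non-site target residues are the negative class); all other residues
    are ``not_target``.

    Raises
    ------
    DataError
        If a position is outside the sequence.
    ConsistencyError
        If the annotated residue letter disagrees with the sequence.
    """
    seqs = _read_fasta(fasta_source)
    rows = _read_annotation_rows(annotation_source)

    labels: dict[str, list[Label]] = {}
    for pid, seq in seqs.items():
        labels[pid] = [
            Label.NONFUNCTIONAL if aa in TARGET_RESIDUES else Label.NOT_TARGET
            for aa in seq
        ]
    for pid, pos, residue, label in rows:
        if pid not in seqs:
            raise DataError(f"annotation for unknown protein {pid!r}")
        seq = seqs[pid]
        if not 1 <= pos <= len(seq):
            raise DataError(
                f"{pid}: annotated position {pos} outside sequence of "
                f"length {len(seq)}")
        if seq[pos - 1] != residue:
            raise ConsistencyError(
                f"{pid} position {pos}: annotation says {residue!r} but "
                f"sequence has {seq[pos - 1]!r}")
        if residue not in TARGET_RESIDUES:
            raise ConsistencyError(
                f"{pid} position {pos}: residue {residue!r} is not one of "
                f"the target types {TARGET_RESIDUES}")
        labels[pid][pos - 1] = label
    return [AnnotatedProtein(pid, seq, labels[pid]) for pid, seq in seqs.items()]


def _read_annotation_rows(source) -> list[tuple[str, int, str, Label]]:
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or (isinstance(source, str)
                                      and "\n" not in source
                                      and "\t" not in source):
        text = Path(source).read_text()
    else:  # raw TSV content
        text = str(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    start = 1 if lines[0].split("\t")[0] == "protein_id" else 0
    rows = []
    for ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise DataError(f"malformed annotation row: {ln!r}")
        pid, pos_s, residue, label_s = parts
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise DataError(f"non-integer position in row {ln!r}") from exc
        try:
            label = Label(label_s)
        except ValueError as exc:
            raise DataError(f"unknown label {label_s!r} in row {ln!r}") from exc
        if label == Label.NOT_TARGET:
            raise DataError(f"label {label_s!r} may not be assigned explicitly")
        rows.append((pid, pos, residue, label))
    return rows


def write_annotations(proteins: Iterable[AnnotatedProtein], fasta_path, annotation_path) -> None:
    """Write FASTA plus annotation TSV (inverse of :func:`read_annotations`).

    Only non-default labels (carbonylation/ligand) are emitted; the
    ``nonfunctional`` default is implicit.
    """
    proteins = list(proteins)
    with open(fasta_path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")
    with open(annotation_path, "w") as fh:
        fh.write("\t".join(ANNOTATION_HEADER) + "\n")
        for p in proteins:
            for i, lab in enumerate(p.labels):
                if lab in (Label.CARBONYLATION, Label.LIGAND):
                    fh.write(f"{p.id}\t{i + 1}\t{p.sequence[i]}\t{lab}\n")


# ---------------------------------------------------------------------------
# Segment extraction


def extract_segments(protein: AnnotatedProtein, residue_type: str,
                     window_size: int = DEFAULT_SEGMENT_LENGTH) -> list[Segment]:
    """One segment per occurrence of ``residue_type``, termini padded with 'X'."""
    if residue_type not in TARGET_RESIDUES:
        raise ConfigurationError(
            f"residue_type must be one of {TARGET_RESIDUES!r}, got {residue_type!r}")
    if window_size % 2 == 0 or window_size < 5:
        raise ConfigurationError(
            f"window_size must be odd and >= 5, got {window_size}")
    w = window_size // 2
    seq = protein.sequence
    out = []
    for pos in protein.target_positions(residue_type):
        lo, hi = pos - w, pos + w + 1
        left_pad = max(0, -lo)
        right_pad = max(0, hi - len(seq))
        window = (PAD_CHAR * left_pad
                  + seq[max(lo, 0):min(hi, len(seq))]
                  + PAD_CHAR * right_pad)
        out.append(Segment(
            protein_id=protein.id,
            center_pos=pos + 1,
            residue_type=residue_type,
            window=window,
            label=protein.labels[pos],
            pad_count=left_pad + right_pad,
        ))
    return out


def crop_window(segment: Segment, window_size: int) -> Segment:
    """Crop a stored segment to a smaller working window (same center)."""
    if window_size % 2 == 0:
        raise ConfigurationError(f"window_size must be odd, got {window_size}")
    if window_size > len(segment.window):
        raise ConfigurationError(
            f"cannot crop length-{len(segment.window)} window to {window_size}")
    if window_size == len(segment.window):
        return segment
    mid = len(segment.window) // 2
    w = window_size // 2
    window = segment.window[mid - w:mid + w + 1]
    return Segment(
        protein_id=segment.protein_id,
        center_pos=segment.center_pos,
        residue_type=segment.residue_type,
        window=window,
        label=segment.label,
        pad_count=window.count(PAD_CHAR),
    )


# ---------------------------------------------------------------------------
# Splitting


def split_dataset(segments: Sequence[Segment], fractions: Sequence[float],
                  seed: int) -> DatasetSplit:
    """Deterministic stratified split preserving per-class proportions.

    ``fractions`` has two (train, validation) or three (train, validation,
    test) entries summing to 1.  Within each class, membership is decided by
    a seeded shuffle followed by cumulative-rounding allocation, so each
    split holds the class's share within one segment.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) not in (2, 3):
        raise ConfigurationError("fractions must have 2 or 3 entries")
    if any(not 0.0 < f < 1.0 for f in fractions):
        raise ConfigurationError(f"each fraction must be in (0,1): {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions must sum to 1: {fractions}")

    rng = np.random.default_rng(seed)
    by_label: dict[Label, list[Segment]] = {}
    for seg in segments:
        by_label.setdefault(seg.label, []).append(seg)

    parts: list[list[Segment]] = [[] for _ in range(len(fractions))]
    for lab in sorted(by_label, key=lambda l: l.value):
        group = by_label[lab]
        order = rng.permutation(len(group))
        cuts = np.round(np.cumsum(fractions) * len(group)).astype(int)
        start = 0
        for k, stop in enumerate(cuts):
            parts[k].extend(group[i] for i in order[start:stop])
            start = stop
    test = parts[2] if len(parts) == 3 else []
    return DatasetSplit(train=parts[0], validation=parts[1], test=test, seed=seed)


# ---------------------------------------------------------------------------
# Segment TSV round trip

SEGMENT_HEADER = ["protein_id", "center_pos", "residue_type", "window", "label", "pad_count"]


def segments_to_tsv(segments: Iterable[Segment], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_HEADER) + "\n")
        for s in segments:
            fh.write(f"{s.protein_id}\t{s.center_pos}\t{s.residue_type}\t"
                     f"{s.window}\t{s.label}\t{s.pad_count}\n")


def segments_from_tsv(path) -> list[Segment]:
    lines = Path(path).read_text().splitlines()
    out = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        pid, pos, rtype, window, label, pad = ln.split("\t")
        out.append(Segment(pid, int(pos), rtype, window, Label(label), int(pad)))
    return out
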