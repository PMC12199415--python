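"""Information-theoretic discovery of carbonylation-related sequence motifs.

Candidate motifs are short wildcard patterns (4–10 residues over the amino
acid alphabet plus 'x' = match-any-residue).  A pattern is kept when it
occurs in more than a threshold fraction T of carbonylation segments and in
fewer than T of random noncarbonylation segment sets (10 replicates, each
the size of the positive set).  Surviving patterns are ranked by an
information gain ratio (IGR): the class-label information gain the pattern
achieves on a positives-plus-replicate union, divided by the gain the same
pattern achieves after the labels are randomly permuted (a null reference,
averaged over the replicates; a permuted-label IG of a single-class set
would be identically zero, so the null union is the denominator that makes
the ratio well defined).  Top-q motifs with their gains form a simple
cumulative-IG scorer: a segment's score is the summed gain of the motifs it
contains.

Entropies are in bits (log base 2); the base cancels in the ratio.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data import AMINO_ACIDS, Label, Segment
from .errors import ConfigurationError, DataError, EvaluationError

__all__ = [
    "MotifCorpus",
    "WildcardPattern",
    "ScoredMotif",
    "MotifModel",
    "MotifDiscovery",
    "build_corpus",
    "entropy",
    "generate_patterns",
    "pattern_frequency",
    "filter_patterns",
    "information_gain",
    "rank_and_select",
    "motif_score",
]

MAX_PATTERN_LENGTH = 10  # L in the pattern-length bound 4 <= l <= L
MIN_PATTERN_LENGTH = 4
N_REPLICATES = 10
DEFAULT_T = 0.05
IGR_FLOOR = 1e-6  # bits; guards the null-gain denominator

_WILDCARD_CLASS = f"[{AMINO_ACIDS}]"


@lru_cache(maxsize=65536)
def _compiled(pattern: str) -> re.Pattern:
    return re.compile("".join(
        _WILDCARD_CLASS if c == "x" else re.escape(c) for c in pattern))


@dataclass(frozen=True)
class WildcardPattern:
    """A pattern over residues plus 'x'; never starts or ends with 'x'."""

    pattern: str

    def __post_init__(self):
        p = self.pattern
        if not MIN_PATTERN_LENGTH <= len(p) <= MAX_PATTERN_LENGTH:
            raise ConfigurationError(
                f"pattern length must be in [{MIN_PATTERN_LENGTH}, "
                f"{MAX_PATTERN_LENGTH}]: {p!r}")
        if p[0] == "x" or p[-1] == "x":
            raise ConfigurationError(
                f"pattern may not start or end with wildcard: {p!r}")
        if any(c != "x" and c not in AMINO_ACIDS for c in p):
            raise ConfigurationError(f"invalid pattern character in {p!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def regex(self) -> re.Pattern:
        return _compiled(self.pattern)

    def matches(self, window: str) -> bool:
        return self.regex().search(window) is not None


@dataclass
class MotifCorpus:
    """Carbonylation segments plus 10 size-matched negative replicates."""

    d_cs: list[Segment]
    d_ncs_replicates: list[list[Segment]]
    seed: int


@dataclass(frozen=True)
class ScoredMotif:
    pattern: WildcardPattern
    ig_cs: float          # bits, true-label gain averaged over replicates
    ig_ncs_mean: float    # bits, permuted-label null gain
    igr: float
    category: str


@dataclass
class MotifModel:
    """Top-q motifs plus the cumulative-IG scoring rule."""

    motifs: list[ScoredMotif] = field(default_factory=list)

    def score(self, segment: Segment | str) -> float:
        window = segment.window if isinstance(segment, Segment) else segment
        return float(sum(m.ig_cs for m in self.motifs if m.pattern.matches(window)))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pattern\tig_cs\tig_ncs_mean\tigr\tcategory\n")
            for m in self.motifs:
                fh.write(f"{m.pattern.pattern}\t{m.ig_cs:.6f}\t"
                         f"{m.ig_ncs_mean:.6f}\t{m.igr:.6f}\t{m.category}\n")

    @classmethod
    def from_tsv(cls, path) -> "MotifModel":
        lines = Path(path).read_text().splitlines()
        motifs = []
        for ln in lines[1:]:
            if not ln.strip():
                continue
            pat, ig, ign, igr, cat = ln.split("\t")
            motifs.append(ScoredMotif(WildcardPattern(pat), float(ig),
                                      float(ign), float(igr), cat))
        return cls(motifs)


def _categorize(igr: float) -> str:
    if igr > 10:
        return "highly"
    if 2 < igr <= 10:
        return "moderately"
    if 1 <= igr < 2:
        return "marginally"
    return "unfavored"


# ---------------------------------------------------------------------------
# Corpus and entropy


def build_corpus(segments: Sequence[Segment], seed: int) -> MotifCorpus:
    """Split segments into positives and 10 size-matched negative draws.

    Each replicate is drawn without replacement from the noncarbonylation
    segments (ligand plus nonfunctional); replicates are independent draws.
    """
    pos = [s for s in segments if s.label == Label.CARBONYLATION]
    neg = [s for s in segments if s.label != Label.CARBONYLATION]
    if len(neg) < len(pos):
        raise DataError(
            f"need at least {len(pos)} noncarbonylation segments for "
            f"replicates, have {len(neg)}")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(N_REPLICATES):
        idx = rng.choice(len(neg), size=len(pos), replace=False)
        reps.append([neg[i] for i in idx])
    return MotifCorpus(d_cs=pos, d_ncs_replicates=reps, seed=seed)


def entropy(class_counts: Sequence[float]) -> float:
    """Shannon entropy in bits of the class distribution given by counts."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise EvaluationError("class counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise EvaluationError("entropy undefined for all-zero counts")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Pattern generation and matching


def generate_patterns(n_patterns: int, length_range: tuple[int, int], seed: int,
                      wildcard_prob: float = 0.3,
                      positive_segments: Sequence[Segment] | None = None,
                      mined_fraction: float = 0.5) -> list[WildcardPattern]:
    """Random candidate patterns, deduplicated, deterministic given seed.

    When ``positive_segments`` is given, a ``mined_fraction`` share of the
    candidates starts from k-mers observed in those segments (so the
    frequency filter has non-vacuous candidates at small corpus sizes); the
    rest are uniform random.  Interior positions are wildcarded
    independently with ``wildcard_prob``.
    """
    lo, hi = length_range
    if lo < MIN_PATTERN_LENGTH or hi > MAX_PATTERN_LENGTH or lo > hi:
        raise ConfigurationError(
            f"length_range must lie within [{MIN_PATTERN_LENGTH}, "
            f"{MAX_PATTERN_LENGTH}]: {length_range}")
    rng = np.random.default_rng(seed)
    windows = None
    if positive_segments:
        windows = [s.window if isinstance(s, Segment) else s
                   for s in positive_segments]
        windows = [w.replace("X", "") for w in windows]
        windows = [w for w in windows if len(w) >= lo]
    seen: set[str] = set()
    out: list[WildcardPattern] = []
    attempts = 0
    while len(out) < n_patterns and attempts < 50 * n_patterns:
        attempts += 1
        length = int(rng.integers(lo, hi + 1))
        if windows and rng.random() < mined_fraction:
            w = windows[rng.integers(len(windows))]
            if len(w) < length:
                continue
            start = int(rng.integers(0, len(w) - length + 1))
            chars = list(w[start:start + length])
        else:
            chars = [AMINO_ACIDS[i]
                     for i in rng.integers(0, 20, size=length)]
        for i in range(1, length - 1):
            if rng.random() < wildcard_prob:
                chars[i] = "x"
        pat = "".join(chars)
        if pat not in seen:
            seen.add(pat)
            out.append(WildcardPattern(pat))
    return out


def pattern_frequency(pattern: WildcardPattern | str,
                      segment_set: Iterable[Segment | str]) -> float:
    """Fraction of segments containing at least one match (presence/absence)."""
    if isinstance(pattern, str):
        pattern = WildcardPattern(pattern)
    windows = [s.window if isinstance(s, Segment) else s for s in segment_set]
    if not windows:
        return 0.0
    rx = pattern.regex()
    return sum(rx.search(w) is not None for w in windows) / len(windows)


def filter_patterns(patterns: Iterable[WildcardPattern], corpus: MotifCorpus,
                    T: float = DEFAULT_T) -> list[WildcardPattern]:
    """Keep patterns with positive-set frequency > T and mean negative < T."""
    if not 0.0 < T < 1.0:
        raise ConfigurationError(f"T must be in (0,1), got {T}")
    kept = []
    for pat in patterns:
        f_cs = pattern_frequency(pat, corpus.d_cs)
        if f_cs <= T:
            continue
        f_ncs = np.mean([pattern_frequency(pat, rep)
                         for rep in corpus.d_ncs_replicates])
        if f_ncs < T:
            kept.append(pat)
    return kept


# ---------------------------------------------------------------------------
# Information gain and ranking


def information_gain(segments: Sequence[Segment | str],
                     labels: Sequence[int],
                     pattern: WildcardPattern | str) -> float:
    """Decision-tree information gain of splitting on pattern presence.

    IG = H(labels) − [f·H(labels | present) + (1−f)·H(labels | absent)]
    with f the presence fraction; in bits, nonnegative up to float error.
    """
    if isinstance(pattern, str):
        pattern = WildcardPattern(pattern)
    windows = [s.window if isinstance(s, Segment) else s for s in segments]
    labels = np.asarray(labels)
    if len(windows) != len(labels):
        raise DataError("segments and labels length mismatch")
    rx = pattern.regex()
    present = np.array([rx.search(w) is not None for w in windows])
    return _ig_from_masks(present, labels)


def _ig_from_masks(present: np.ndarray, labels: np.ndarray) -> float:
    classes = np.unique(labels)
    h_total = entropy([(labels == c).sum() for c in classes])
    f = present.mean()
    h_split = 0.0
    for mask, weight in ((present, f), (~present, 1.0 - f)):
        if weight > 0:
            h_split += weight * entropy(
                [(labels[mask] == c).sum() for c in classes])
    return h_total - h_split


def rank_and_select(patterns: Sequence[WildcardPattern], corpus: MotifCorpus,
                    q: int = 50) -> MotifModel:
    """Score patterns by IGR over the corpus and keep the top q.

    Per replicate τ, the true-label gain is computed on D_cs ∪ replicate-τ
    (positives labeled 1); the null gain is computed on the same union with
    labels permuted by a replicate-specific seeded shuffle.  Both are
    averaged over the 10 replicates; IGR is their ratio with a small floor
    on the denominator.  Sorting: IGR descending, ties by true gain then by
    pattern string.
    """
    if not patterns:
        import warnings
        warnings.warn("no surviving patterns; returning empty motif model")
        return MotifModel([])
    rng = np.random.default_rng(corpus.seed + 1)
    n_pos = len(corpus.d_cs)
    perms = [rng.permutation(n_pos + len(rep))
             for rep in corpus.d_ncs_replicates]
    pos_windows = [s.window for s in corpus.d_cs]
    rep_windows = [[s.window for s in rep] for rep in corpus.d_ncs_replicates]
    scored = []
    for pat in patterns:
        rx = pat.regex()
        pres_pos = np.array([rx.search(w) is not None for w in pos_windows])
        gains, nulls = [], []
        for rep_w, perm in zip(rep_windows, perms):
            pres_rep = np.array([rx.search(w) is not None for w in rep_w])
            presence = np.concatenate([pres_pos, pres_rep])
            labels = np.concatenate([np.ones(n_pos, dtype=int),
                                     np.zeros(len(rep_w), dtype=int)])
            gains.append(_ig_from_masks(presence, labels))
            nulls.append(_ig_from_masks(presence, labels[perm]))
        ig_cs = float(np.mean(gains))
        ig_ncs = float(np.mean(nulls))
        igr = ig_cs / max(ig_ncs, IGR_FLOOR)
        scored.append(ScoredMotif(pat, ig_cs, ig_ncs, igr, _categorize(igr)))
    scored.sort(key=lambda m: (-m.igr, -m.ig_cs, m.pattern.pattern))
    return MotifModel(scored[:q])


def motif_score(segment: Segment | str, model: MotifModel) -> float:
    """Cumulative gain of the model motifs present in the segment."""
    return model.score(segment)


# ---------------------------------------------------------------------------
# Estimator facade


class MotifDiscovery:
    """Estimator running the full pipeline: corpus → candidates → filter → rank.

    Parameters mirror the pipeline knobs; after :meth:`fit`, ``model_``
    holds the ranked :class:`MotifModel` and :meth:`score_samples` returns
    the cumulative-IG score per segment.
    """

    def __init__(self, n_patterns: int = 2000,
                 length_range: tuple[int, int] = (4, 10),
                 T: float = DEFAULT_T, q: int = 50,
                 wildcard_prob: float = 0.3, mined_fraction: float = 0.5,
                 seed: int = 0):
        self.n_patterns = n_patterns
        self.length_range = length_range
        self.T = T
        self.q = q
        self.wildcard_prob = wildcard_prob
        self.mined_fraction = mined_fraction
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_patterns", "length_range", "T", "q", "wildcard_prob",
                 "mined_fraction", "seed")}

    def set_params(self, **params) -> "MotifDiscovery":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ConfigurationError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, segments: Sequence[Segment]) -> "MotifDiscovery":
        corpus = build_corpus(segments, self.seed)
        candidates = generate_patterns(
            self.n_patterns, self.length_range, self.seed,
            wildcard_prob=self.wildcard_prob,
            positive_segments=corpus.d_cs,
            mined_fraction=self.mined_fraction)
        survivors = filter_patterns(candidates, corpus, self.T)
        self.corpus_ = corpus
        self.n_candidates_ = len(candidates)
        self.n_survivors_ = len(survivors)
        self.model_ = rank_and_select(survivors, corpus, self.q)
        return self

    def score_samples(self, segments: Iterable[Segment | str]) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ConfigurationError("MotifDiscovery is not fitted")
        return np.array([self.model_.score(s) for s in segments])
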