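"""Motif discovery: entropy, pattern machinery, information gain, ranking."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scans.data import Label, Segment
from scans.errors import ConfigurationError, DataError, EvaluationError
from scans.motifs import (
    MotifDiscovery,
    MotifModel,
    ScoredMotif,
    WildcardPattern,
    build_corpus,
    entropy,
    filter_patterns,
    generate_patterns,
    information_gain,
    motif_score,
    pattern_frequency,
    rank_and_select,
)


def seg(window, label=Label.NONFUNCTIONAL, pid="P", pos=None):
    mid = len(window) // 2
    pos = pos if pos is not None else mid + 1
    return Segment(pid, pos, window[mid], window, label, 0)


def brute_force_ig(windows, labels, pattern):
    """Independent oracle: enumerate the 2x2 contingency table directly."""
    rx = WildcardPattern(pattern).regex() if isinstance(pattern, str) else pattern.regex()
    present = [rx.search(w) is not None for w in windows]

    def h(counts):
        total = sum(counts)
        return -sum(c / total * math.log2(c / total) for c in counts if c)

    n = len(windows)
    h_d = h([sum(labels), n - sum(labels)])
    out = h_d
    for flag in (True, False):
        idx = [i for i in range(n) if present[i] == flag]
        if idx:
            pos = sum(labels[i] for i in idx)
            out -= len(idx) / n * h([pos, len(idx) - pos])
    return out


class TestEntropy:
    @pytest.mark.parametrize("counts,expected", [
        ((50, 50), 1.0),
        ((100, 0), 0.0),
        ((25, 75), 0.8112781244591328),  # -(1/4 log2 1/4 + 3/4 log2 3/4)
    ])
    def test_known_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_counts_undefined(self):
        with pytest.raises(EvaluationError):
            entropy((0, 0))


class TestCorpus:
    def _segments(self, n_pos, n_neg):
        pos = [seg("AAKAA", Label.CARBONYLATION, pid=f"p{i}") for i in range(n_pos)]
        neg = [seg("CCKCC", Label.NONFUNCTIONAL, pid=f"n{i}") for i in range(n_neg)]
        return pos + neg

    def test_replicates_match_positive_count(self):
        corpus = build_corpus(self._segments(50, 500), seed=1)
        assert len(corpus.d_cs) == 50
        assert len(corpus.d_ncs_replicates) == 10
        assert all(len(r) == 50 for r in corpus.d_ncs_replicates)

    def test_deterministic_membership(self):
        segs = self._segments(20, 100)
        a = build_corpus(segs, seed=3)
        b = build_corpus(segs, seed=3)
        assert [[s.protein_id for s in r] for r in a.d_ncs_replicates] == \
               [[s.protein_id for s in r] for r in b.d_ncs_replicates]

    def test_insufficient_negatives_is_data_error(self):
        with pytest.raises(DataError, match="50"):
            build_corpus(self._segments(50, 40), seed=0)


class TestPatterns:
    def test_lengths_within_bounds_and_no_terminal_wildcards(self):
        pats = generate_patterns(300, (4, 10), seed=2, wildcard_prob=0.5)
        assert pats
        for p in pats:
            assert 4 <= len(p) <= 10
            assert p.pattern[0] != "x" and p.pattern[-1] != "x"

    def test_zero_wildcard_probability(self):
        pats = generate_patterns(100, (4, 8), seed=2, wildcard_prob=0.0)
        assert all("x" not in p.pattern for p in pats)

    def test_deterministic_and_deduplicated(self):
        a = generate_patterns(200, (4, 10), seed=9)
        b = generate_patterns(200, (4, 10), seed=9)
        assert [p.pattern for p in a] == [p.pattern for p in b]
        assert len({p.pattern for p in a}) == len(a)

    def test_length_outside_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_patterns(10, (3, 10), seed=0)
        with pytest.raises(ConfigurationError):
            WildcardPattern("ACA")  # length 3

    def test_frequency_examples(self):
        assert pattern_frequency("AKxKA", ["CAKAKAC", "CCCCCCC"]) == 0.5
        assert pattern_frequency("AAAAAAAAAA", ["CACAC"]) == 0.0
        # wildcard never matches the terminal padding character
        assert pattern_frequency("AxAA", ["AXAA"]) == 0.0
        assert pattern_frequency("AxAA", ["AGAA"]) == 1.0


class TestFilter:
    def _corpus(self, pos_windows, neg_windows):
        pos = [seg(w, Label.CARBONYLATION, pid=f"p{i}")
               for i, w in enumerate(pos_windows)]
        neg = [seg(w, Label.NONFUNCTIONAL, pid=f"n{i}")
               for i, w in enumerate(neg_windows)]
        return build_corpus(pos + neg * 10, seed=0)

    def test_keeps_enriched_drops_shared_and_boundary(self):
        pos = ["AAKQQQA"] * 4 + ["CCKCCCC"] * 16
        neg = ["CCKCCCC"] * 20
        corpus = self._corpus(pos, neg)
        kept = filter_patterns([WildcardPattern("AKQQ")], corpus, T=0.05)
        assert [p.pattern for p in kept] == ["AKQQ"]
        # frequency equal to T on the positive side is dropped (strict >)
        pos_b = ["AAKQQQA"] * 1 + ["CCKCCCC"] * 19  # f_cs = 0.05 exactly
        corpus_b = self._corpus(pos_b, neg)
        assert filter_patterns([WildcardPattern("AKQQ")], corpus_b, T=0.05) == []
        # common pattern fails the negative-side inequality
        assert filter_patterns([WildcardPattern("CKCC")], corpus, T=0.05) == []


class TestInformationGain:
    def test_perfect_split_of_balanced_set_is_one_bit(self):
        windows = ["AAQWEAA"] * 10 + ["CCCCCCC"] * 10
        labels = [1] * 10 + [0] * 10
        assert information_gain(windows, labels, "QWEA") == pytest.approx(1.0)

    def test_absent_pattern_gives_zero(self):
        windows = ["AAAAA"] * 5 + ["CCCCC"] * 5
        assert information_gain(windows, [1] * 5 + [0] * 5, "WWWW") == 0.0

    def test_matches_contingency_oracle_on_random_instances(self, rng):
        alphabet = list("ACDE")
        for trial in range(30):
            n = int(rng.integers(10, 200))
            windows = ["".join(rng.choice(alphabet, size=9)) for _ in range(n)]
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            pattern = "".join(rng.choice(alphabet, size=4))
            got = information_gain(windows, labels, pattern)
            want = brute_force_ig(windows, list(labels), pattern)
            assert got == pytest.approx(want, abs=1e-12)
            assert got >= -1e-12

    def test_monotone_in_positive_frequency(self):
        # planting the pattern in more positives never lowers the gain
        neg = ["CCCCCCC"] * 50
        gains = []
        for k in (5, 15, 30, 45):
            pos = ["AAQWEAA"] * k + ["GGGGGGG"] * (50 - k)
            gains.append(information_gain(pos + neg, [1] * 50 + [0] * 50, "QWEA"))
        assert all(b >= a - 1e-12 for a, b in zip(gains, gains[1:]))


class TestRanking:
    def test_tie_break_by_gain_then_pattern(self):
        a = ScoredMotif(WildcardPattern("AAAA"), 0.3, 0.01, 5.0, "moderately")
        b = ScoredMotif(WildcardPattern("CCCC"), 0.5, 0.01, 5.0, "moderately")
        order = sorted([a, b], key=lambda m: (-m.igr, -m.ig_cs, m.pattern.pattern))
        assert order[0].pattern.pattern == "CCCC"

    def test_q_larger_than_survivors_returns_all(self):
        pos = [seg("AAQWEAA", Label.CARBONYLATION, pid=f"p{i}") for i in range(20)]
        neg = [seg("CCCCCCC", Label.NONFUNCTIONAL, pid=f"n{i}") for i in range(200)]
        corpus = build_corpus(pos + neg, seed=1)
        model = rank_and_select([WildcardPattern("QWEA")], corpus, q=50)
        assert len(model.motifs) == 1

    def test_empty_pattern_set_warns_and_returns_empty_model(self):
        pos = [seg("AAQWEAA", Label.CARBONYLATION)]
        neg = [seg("CCCCCCC", Label.NONFUNCTIONAL) for _ in range(10)]
        corpus = build_corpus(pos + neg, seed=1)
        with pytest.warns(UserWarning):
            model = rank_and_select([], corpus, q=5)
        assert model.motifs == []

    def test_clean_planted_motif_is_highly_favored(self):
        pos = [seg("AAQWEAA", Label.CARBONYLATION, pid=f"p{i}") for i in range(30)]
        neg = [seg("CCCCCCC", Label.NONFUNCTIONAL, pid=f"n{i}") for i in range(400)]
        corpus = build_corpus(pos + neg, seed=2)
        model = rank_and_select([WildcardPattern("QWEA")], corpus, q=5)
        assert model.motifs[0].category == "highly"


class TestScoring:
    def _model(self):
        return MotifModel([
            ScoredMotif(WildcardPattern("QWEA"), 0.3, 0.01, 30.0, "highly"),
            ScoredMotif(WildcardPattern("DDDD"), 0.2, 0.01, 20.0, "highly"),
        ])

    def test_no_match_scores_zero(self):
        assert motif_score("CCCCCCC", self._model()) == 0.0

    def test_cumulative_gain_is_additive(self):
        assert motif_score("QWEADDDD", self._model()) == pytest.approx(0.5)
        assert motif_score("AAQWEAAA", self._model()) == pytest.approx(0.3)

    def test_model_tsv_round_trip(self, tmp_path):
        model = self._model()
        path = tmp_path / "motifs.tsv"
        model.to_tsv(path)
        back = MotifModel.from_tsv(path)
        assert [m.pattern.pattern for m in back.motifs] == ["QWEA", "DDDD"]
        assert back.motifs[0].ig_cs == pytest.approx(0.3, abs=1e-6)


def test_discovery_pipeline_recovers_planted_motif(small_segments):
    """End-to-end: a motif planted by the generator ranks near the top."""
    from scans.data import crop_window
    from scans.simulate import SimulationConfig, simulate_proteins
    from scans.data import extract_segments
    cfg = SimulationConfig(n_proteins=120, length_range=(100, 180),
                           class_props=(0.05, 0.10, 0.85), plant_prob=0.6,
                           planted_motifs=("LQSGE",), seed=13)
    prots = simulate_proteins(cfg)
    segs = [crop_window(s, 13) for p in prots for rt in "KPRT"
            for s in extract_segments(p, rt, 27)]
    disc = MotifDiscovery(n_patterns=3000, wildcard_prob=0.15,
                          mined_fraction=0.7, q=20, seed=13).fit(segs)
    top = [m.pattern.pattern for m in disc.model_.motifs]
    assert any(t in "LQSGE" or "LQSGE" in t for t in top)
    scores = disc.score_samples(segs)
    assert scores.shape == (len(segs),)
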