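"""Cross-prediction-aware metrics against independent oracles."""

import numpy as np
import pytest

from scans.errors import ConfigurationError, EvaluationError
from scans.metrics import (
    aulc_ratio,
    bootstrap_significance,
    confusion_counts,
    confusion_metrics,
    cross_over_rates,
    curves_and_areas,
    evaluate_predictions,
    threshold_optima,
)

CARB, LIGAND, NONFUNC = 0, 1, 2


def mann_whitney_auroc(scores, y_bin):
    """Pair-counting oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[y_bin == 1]
    neg = scores[y_bin == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_three_class(rng, n=2000, props=(0.02, 0.06, 0.92)):
    y = rng.choice([CARB, LIGAND, NONFUNC], size=n, p=props)
    return rng.random(n), y


class TestConfusion:
    def test_perfect_prediction(self):
        m = confusion_metrics(confusion_counts([1, 1, 0, 0],
                                               [CARB, CARB, NONFUNC, LIGAND],
                                               threshold=0.5))
        assert all(m[k] == 1.0 for k in ("SN", "SP", "ACC", "F1", "MCC"))

    def test_formula_values(self):
        from scans.metrics import ConfusionCounts
        m = confusion_metrics(ConfusionCounts(tp=8, fn=2, tn=90, fp=10))
        assert m["SN"] == pytest.approx(0.8)
        assert m["SP"] == pytest.approx(0.9)
        assert m["F1"] == pytest.approx(16 / (16 + 10 + 2))
        want_mcc = (8 * 90 - 2 * 10) / np.sqrt(10 * 18 * 100 * 92)
        assert m["MCC"] == pytest.approx(want_mcc)

    def test_all_negative_prediction(self):
        y = [CARB, NONFUNC, NONFUNC]
        m = confusion_metrics(confusion_counts([0.1, 0.2, 0.3], y, threshold=2.0))
        assert m["SN"] == 0.0 and m["SP"] == 1.0 and m["MCC"] == 0.0

    def test_fp_decomposition(self):
        c = confusion_counts([1, 1, 1, 0], [CARB, LIGAND, NONFUNC, NONFUNC], 0.5)
        assert c.fp == c.fp_ligand + c.fp_nonfunctional == 2


class TestCrossOverRates:
    def test_ratio_arithmetic(self):
        # 3/5 carb above threshold, 3/10 ligand above: ratio 2
        scores = ([0.9] * 3 + [0.1] * 2          # carb
                  + [0.9] * 3 + [0.1] * 7        # ligand
                  + [0.1] * 10)                  # nonfunctional
        y = [CARB] * 5 + [LIGAND] * 10 + [NONFUNC] * 10
        out = cross_over_rates(scores, y, threshold=0.5)
        assert out["SN"] == pytest.approx(0.6)
        assert out["CPR"] == pytest.approx(0.3)
        assert out["CPRratio"] == pytest.approx(2.0)

    def test_random_scores_give_ratios_near_one(self, rng):
        ratios_c, ratios_o = [], []
        for _ in range(20):
            s, y = random_three_class(rng, n=5000)
            out = cross_over_rates(s, y, threshold=0.9)
            ratios_c.append(out["CPRratio"])
            ratios_o.append(out["OPRratio"])
        assert np.mean(ratios_c) == pytest.approx(1.0, abs=0.15)
        assert np.mean(ratios_o) == pytest.approx(1.0, abs=0.1)

    def test_zero_rate_floored_and_flagged(self):
        scores = [0.9, 0.9, 0.1, 0.1, 0.1]
        y = [CARB, CARB, LIGAND, LIGAND, NONFUNC]
        out = cross_over_rates(scores, y, threshold=0.5)
        assert out["CPR"] == 0.0
        assert out["CPRratio"] == pytest.approx(1.0 / (1.0 / 4))  # SN=1 over eps=1/4
        assert "CPR_floored" in out["flags"]

    def test_absent_ligand_class_reported_absent(self):
        out = cross_over_rates([0.9, 0.1], [CARB, NONFUNC], threshold=0.5)
        assert out["CPR"] is None and out["CPRratio"] is None
        assert "CPR_absent" in out["flags"]


class TestCurves:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.3, 0.2, 0.1]
        y = [CARB, CARB, LIGAND, NONFUNC, NONFUNC]
        _, areas = curves_and_areas(scores, y)
        assert areas["AUROC"] == 1.0
        assert areas["AUCPC"] == pytest.approx(0.0)
        assert areas["AUOPC"] == pytest.approx(0.0)

    def test_random_scores_areas_near_half(self, rng):
        s, y = random_three_class(rng, n=10000)
        _, areas = curves_and_areas(s, y)
        assert areas["AUROC"] == pytest.approx(0.5, abs=0.06)
        assert areas["AUCPC"] == pytest.approx(0.5, abs=0.08)
        assert areas["AUOPC"] == pytest.approx(0.5, abs=0.06)

    def test_constant_scores_handled(self):
        scores = [0.3] * 6
        y = [CARB, CARB, LIGAND, NONFUNC, NONFUNC, NONFUNC]
        curves, areas = curves_and_areas(scores, y)
        assert np.isfinite(areas["AUROC"])

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            curves_and_areas([0.1, 0.2], [CARB, CARB])

    def test_auroc_equals_pair_counting_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 500))
            scores = rng.choice(np.linspace(0, 1, 17), size=n)  # force ties
            y = (rng.random(n) < 0.3).astype(int)
            if y.sum() in (0, n):
                y[0] = 1 - y[0]
            labels = np.where(y == 1, CARB, NONFUNC)
            _, areas = curves_and_areas(scores, labels)
            assert areas["AUROC"] == pytest.approx(
                mann_whitney_auroc(scores, y), abs=1e-10)

    def test_rank_metrics_invariant_under_monotone_transform(self, rng):
        s, y = random_three_class(rng, n=800)
        _, a1 = curves_and_areas(s, y)
        _, a2 = curves_and_areas(np.exp(3 * s) + 7, y)
        for key in ("AUROC", "AUPRC", "AUCPC", "AUOPC"):
            assert a1[key] == pytest.approx(a2[key], abs=1e-12)


class TestAulc:
    def test_perfect_scores_rectangle(self):
        y = [CARB] * 5 + [NONFUNC] * 95
        scores = np.concatenate([np.linspace(0.9, 1, 5), np.linspace(0, 0.5, 95)])
        for c in (0.05, 0.1, 0.5):
            aulc, ratio = aulc_ratio(scores, y, c)
            assert aulc == pytest.approx(c, abs=1e-12)
            assert ratio == pytest.approx(2 / c, abs=1e-9)

    def test_random_scores_ratio_near_one(self, rng):
        vals = []
        for _ in range(10):
            s, y = random_three_class(rng, n=5000, props=(0.2, 0.0, 0.8))
            vals.append(aulc_ratio(s, y, 0.1)[1])
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_full_range_equals_auroc_scale(self, rng):
        s, y = random_three_class(rng, n=3000, props=(0.3, 0.0, 0.7))
        aulc, ratio = aulc_ratio(s, y, 1.0)
        _, areas = curves_and_areas(s, y)
        assert aulc == pytest.approx(areas["AUROC"], abs=1e-12)
        assert ratio == pytest.approx(2 * areas["AUROC"], abs=1e-9)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ConfigurationError):
            aulc_ratio([0.1, 0.9], [CARB, NONFUNC], 0.0)


def brute_force_optima(scores, y_bin):
    """Exhaustive enumeration over all distinct thresholds."""
    best_mcc, best_f1 = -2.0, -1.0
    for t in sorted(set(scores)):
        pred = scores >= t
        tp = int((pred & (y_bin == 1)).sum())
        fp = int((pred & (y_bin == 0)).sum())
        fn = int((~pred & (y_bin == 1)).sum())
        tn = int((~pred & (y_bin == 0)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fn * fp) / np.sqrt(denom) if denom else 0.0
        best_mcc, best_f1 = max(best_mcc, mcc), max(best_f1, f1)
    return best_mcc, best_f1


class TestThresholdOptima:
    def test_perfect_scores(self):
        y = [CARB, CARB, NONFUNC, NONFUNC]
        out = threshold_optima([0.9, 0.8, 0.2, 0.1], y)
        assert out["MCCmax"] == 1.0 and out["F1max"] == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(10, 1000))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)
            y_bin = (rng.random(n) < 0.2).astype(int)
            if y_bin.sum() in (0, n):
                y_bin[0] = 1 - y_bin[0]
            labels = np.where(y_bin == 1, CARB, NONFUNC)
            out = threshold_optima(scores, labels)
            want_mcc, want_f1 = brute_force_optima(scores, y_bin)
            assert out["MCCmax"] == pytest.approx(want_mcc, abs=1e-10)
            assert out["F1max"] == pytest.approx(want_f1, abs=1e-10)

    def test_sn_at_specificity_anchor(self):
        # 10 negatives: threshold keeping 1 FP has SP=0.9
        scores = np.array([0.95, 0.85, 0.9] + [0.5, 0.4, 0.3, 0.2, 0.15,
                                               0.1, 0.08, 0.05, 0.03, 0.7])
        labels = np.array([CARB, CARB, NONFUNC] + [NONFUNC] * 10)
        labels[-1] = NONFUNC
        out = threshold_optima(scores, labels, sp_targets=(0.90,))
        assert out["sn_at_sp"][0.90] == pytest.approx(1.0)

    def test_unreachable_target_flagged(self):
        out = threshold_optima([0.5, 0.5, 0.5, 0.5],
                               [CARB, NONFUNC, NONFUNC, NONFUNC],
                               sp_targets=(0.95,))
        assert out["sn_at_sp"][0.95] is None
        assert "SP_0.95_unreachable" in out["flags"]


class TestBootstrap:
    def test_identical_predictors_not_significant(self, rng):
        s, y = random_three_class(rng, n=500, props=(0.1, 0.1, 0.8))
        rep = bootstrap_significance(s, s, y, seed=1)
        assert rep["AUROC"]["p_value"] == pytest.approx(1.0)
        assert not rep["AUROC"]["significant"]

    def test_perfect_vs_random_is_significant(self, rng):
        y = np.array([CARB] * 50 + [NONFUNC] * 450)
        perfect = np.where(y == CARB, 1.0, 0.0) + rng.normal(0, 1e-3, 500)
        random = rng.random(500)
        rep = bootstrap_significance(perfect, random, y, seed=2)
        assert rep["AUROC"]["p_value"] < 0.001
        assert rep["AUROC"]["significant"]
        assert rep["AUROC"]["mean_a"] > 0.99

    def test_same_seed_reproduces_report(self, rng):
        s, y = random_three_class(rng, n=400, props=(0.1, 0.1, 0.8))
        s2 = np.clip(s + rng.normal(0, 0.2, 400), 0, 1)
        a = bootstrap_significance(s, s2, y, seed=5)
        b = bootstrap_significance(s, s2, y, seed=5)
        assert a == b

    def test_too_few_replicates_rejected(self, rng):
        s, y = random_three_class(rng, n=100, props=(0.2, 0.2, 0.6))
        with pytest.raises(ConfigurationError):
            bootstrap_significance(s, s, y, n_reps=1)


def test_curve_tsv_export(tmp_path, rng):
    from scans.metrics import curves_to_tsv
    s, y = random_three_class(rng, n=300, props=(0.1, 0.1, 0.8))
    curves, _ = curves_and_areas(s, y)
    path = tmp_path / "curves.tsv"
    curves_to_tsv(curves, path)
    lines = path.read_text().splitlines()
    assert lines[0] == "curve\tx\ty"
    names = {ln.split("\t")[0] for ln in lines[1:]}
    assert names == {"roc", "pr", "cp", "op"}


def test_full_report_assembles(rng):
    s, y = random_three_class(rng, n=2000)
    report = evaluate_predictions(s, y, threshold=0.9)
    for key in ("AUROC", "AUPRC", "AUCPC", "AUOPC", "MCCmax", "F1max",
                "AULC@0.05", "AULCratio@0.1", "sn_at_sp", "rates_at_sp"):
        assert key in report
    assert 0 <= report["at_threshold"]["SN"] <= 1
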