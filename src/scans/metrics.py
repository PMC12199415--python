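"""Cross-prediction-aware evaluation of carbonylation-site predictors.

Beyond the standard confusion metrics (SN, SP, ACC, F1, MCC) and curves
(ROC, PR), false positives are decomposed by what they actually are:

* cross-predictions — ligand interaction sites called carbonylation sites;
  their per-class rate is CPR (fraction of ligand-labeled residues
  predicted positive);
* overpredictions — nonfunctional residues called carbonylation sites;
  their rate is OPR.

CPRratio = SN / CPR and OPRratio = SN / OPR calibrate against chance: a
scorer with no information flags every class at the same rate, so both
ratios are 1; larger is better.  The CP (resp. OP) curve plots CPR (resp.
OPR) against SN over the shared threshold sweep; its area AUCPC (AUOPC) is
0.5 for a random scorer and 0 for a predictor that finds every true site
before flagging a single ligand (nonfunctional) residue — lower is better.
AULC is the partial area under the ROC curve at low false positive rates;
AULCratio divides it by the random reference cutoff²/2.

Label convention: integer codes 0 = carbonylation (positive class),
1 = ligand, 2 = nonfunctional, as in :data:`scans.features.LABEL_INDEX`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

from .data import Label
from .errors import ConfigurationError, EvaluationError
from .features import LABEL_INDEX

__all__ = [
    "ConfusionCounts",
    "CurveSet",
    "confusion_counts",
    "confusion_metrics",
    "cross_over_rates",
    "curves_and_areas",
    "curves_to_tsv",
    "aulc_ratio",
    "threshold_optima",
    "bootstrap_significance",
    "evaluate_predictions",
]

CARB, LIGAND, NONFUNC = 0, 1, 2


def _codes(labels) -> np.ndarray:
    labels = list(labels)
    if labels and isinstance(labels[0], Label):
        return np.array([LABEL_INDEX[l] for l in labels], dtype=int)
    return np.asarray(labels, dtype=int)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    fp_ligand: int = 0
    fp_nonfunctional: int = 0

    def __post_init__(self):
        if self.fp_ligand or self.fp_nonfunctional:
            if self.fp != self.fp_ligand + self.fp_nonfunctional:
                raise EvaluationError(
                    "FP decomposition does not sum to FP")


def confusion_counts(scores, labels, threshold: float) -> ConfusionCounts:
    """Counts at a threshold (predicted positive when score >= threshold)."""
    y = _codes(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    pos = y == CARB
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
        fp_ligand=int((pred & (y == LIGAND)).sum()),
        fp_nonfunctional=int((pred & (y == NONFUNC)).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """SN, SP, ACC, F1, MCC from confusion counts (MCC = 0 when undefined)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    if total == 0:
        raise EvaluationError("empty dataset")
    if tp + fn == 0 or tn + fp == 0:
        raise EvaluationError("need at least one positive and one negative")
    sn = tp / (tp + fn)
    sp = tn / (tn + fp)
    acc = (tp + tn) / total
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fn * fp) / np.sqrt(denom)) if denom > 0 else 0.0
    return {"SN": sn, "SP": sp, "ACC": acc, "F1": f1, "MCC": float(mcc)}


def cross_over_rates(scores, labels, threshold: float,
                     precision_style: bool = False) -> dict:
    """CPR, OPR and their sensitivity ratios at a threshold.

    The rate reading is the default: CPR is the fraction of ligand-labeled
    residues predicted positive (analogously OPR for nonfunctional), which
    is the only reading under which a random scorer has both ratios equal
    to 1.  ``precision_style=True`` instead divides by the number of
    predicted positives.  A zero rate is floored at half a count
    (1/(2·class size)) before the ratio and flagged.
    """
    y = _codes(labels)
    s = np.asarray(scores, dtype=float)
    pred = s >= threshold
    out: dict = {"threshold": threshold, "flags": []}
    n_pos = int((y == CARB).sum())
    if n_pos == 0:
        raise EvaluationError("no carbonylation-labeled residues")
    sn = float((pred & (y == CARB)).sum() / n_pos)
    out["SN"] = sn
    n_pred = int(pred.sum())
    for name, cls in (("CPR", LIGAND), ("OPR", NONFUNC)):
        n_cls = int((y == cls).sum())
        if n_cls == 0:
            out[name] = None
            out[f"{name}ratio"] = None
            out["flags"].append(f"{name}_absent")
            continue
        hits = int((pred & (y == cls)).sum())
        rate = hits / n_pred if (precision_style and n_pred > 0) else hits / n_cls
        out[name] = rate
        if rate == 0.0:
            eps = 1.0 / (2 * n_cls)
            out[f"{name}ratio"] = sn / eps
            out["flags"].append(f"{name}_floored")
        else:
            out[f"{name}ratio"] = sn / rate
    return out


# ---------------------------------------------------------------------------
# Curves


@dataclass
class CurveSet:
    thresholds: np.ndarray          # descending sweep
    roc: tuple[np.ndarray, np.ndarray]   # (FPR, TPR)
    pr: tuple[np.ndarray, np.ndarray]    # (recall, precision)
    cp: tuple[np.ndarray, np.ndarray]    # (SN, CPR)
    op: tuple[np.ndarray, np.ndarray]    # (SN, OPR)
    flags: list[str] = field(default_factory=list)


def _sweep(scores: np.ndarray, y: np.ndarray):
    """Shared descending threshold sweep; tied scores move together."""
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    # indices where a threshold can sit (strictly between distinct scores)
    distinct = np.where(np.diff(s_sorted) != 0)[0]
    cut_after = np.concatenate([distinct, [len(s_sorted) - 1]])  # inclusive
    is_pos = (y_sorted == CARB).astype(float)
    is_lig = (y_sorted == LIGAND).astype(float)
    is_non = (y_sorted == NONFUNC).astype(float)
    cum_pos = np.cumsum(is_pos)[cut_after]
    cum_lig = np.cumsum(is_lig)[cut_after]
    cum_non = np.cumsum(is_non)[cut_after]
    thresholds = s_sorted[cut_after]
    return thresholds, cum_pos, cum_lig, cum_non


def curves_and_areas(scores, labels) -> tuple[CurveSet, dict[str, float]]:
    """All four curves over a shared sweep, plus their areas.

    ROC/PR use the standard estimators (trapezoidal AUROC, step-wise
    AUPRC).  The CP and OP curves plot the per-class error rate against SN;
    both are anchored at (0,0) and (1,1) and integrated by the trapezoid
    rule over SN.
    """
    y = _codes(labels)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise EvaluationError("scores must be finite")
    y_bin = (y == CARB).astype(int)
    if y_bin.sum() == 0 or y_bin.sum() == len(y_bin):
        raise EvaluationError("curves undefined: labels are single-class")

    thresholds, cum_pos, cum_lig, cum_non = _sweep(s, y)
    n_pos = (y == CARB).sum()
    n_lig = (y == LIGAND).sum()
    n_non = (y == NONFUNC).sum()
    sn = np.concatenate([[0.0], cum_pos / n_pos])
    cpr = (np.concatenate([[0.0], cum_lig / n_lig])
           if n_lig > 0 else None)
    opr = (np.concatenate([[0.0], cum_non / n_non])
           if n_non > 0 else None)

    fpr, tpr, _ = roc_curve(y_bin, s)
    from sklearn.metrics import precision_recall_curve
    precision, recall, _ = precision_recall_curve(y_bin, s)

    areas = {
        "AUROC": float(roc_auc_score(y_bin, s)),
        "AUPRC": float(average_precision_score(y_bin, s)),
    }
    flags = []
    if cpr is not None:
        areas["AUCPC"] = float(np.trapezoid(cpr, sn))
    else:
        areas["AUCPC"] = None
        flags.append("CPR_absent")
    if opr is not None:
        areas["AUOPC"] = float(np.trapezoid(opr, sn))
    else:
        areas["AUOPC"] = None
        flags.append("OPR_absent")

    curves = CurveSet(
        thresholds=thresholds,
        roc=(fpr, tpr),
        pr=(recall, precision),
        cp=(sn, cpr if cpr is not None else np.full_like(sn, np.nan)),
        op=(sn, opr if opr is not None else np.full_like(sn, np.nan)),
        flags=flags,
    )
    return curves, areas


def aulc_ratio(scores, labels, fpr_cutoff: float) -> tuple[float, float]:
    """Partial area under the ROC curve for FPR in [0, cutoff], and its
    ratio to the random reference cutoff²/2."""
    if not 0.0 < fpr_cutoff <= 1.0:
        raise ConfigurationError(f"fpr_cutoff must be in (0,1]: {fpr_cutoff}")
    y = _codes(labels)
    y_bin = (y == CARB).astype(int)
    if y_bin.sum() == 0 or y_bin.sum() == len(y_bin):
        raise EvaluationError("curves undefined: labels are single-class")
    fpr, tpr, _ = roc_curve(y_bin, np.asarray(scores, dtype=float))
    if fpr_cutoff < fpr[-1]:
        tpr_at = np.interp(fpr_cutoff, fpr, tpr)
        keep = fpr <= fpr_cutoff
        fx = np.concatenate([fpr[keep], [fpr_cutoff]])
        fy = np.concatenate([tpr[keep], [tpr_at]])
    else:
        fx, fy = fpr, tpr
    aulc = float(np.trapezoid(fy, fx))
    return aulc, aulc / (fpr_cutoff**2 / 2.0)


def threshold_optima(scores, labels,
                     sp_targets: tuple[float, ...] = (0.95, 0.90)) -> dict:
    """Exhaustive sweep over score thresholds.

    Returns the maximum MCC and F1 over thresholds, and SN anchored at each
    specificity target (the admissible threshold maximizing SN subject to
    SP >= target; ties resolved toward higher SP).  An unreachable target is
    reported as None with a flag.
    """
    y = _codes(labels)
    s = np.asarray(scores, dtype=float)
    pos = y == CARB
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("need both classes for threshold sweep")
    thresholds, cum_pos, _, _ = _sweep(s, y)
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    distinct = np.where(np.diff(s_sorted) != 0)[0]
    cut_after = np.concatenate([distinct, [len(s_sorted) - 1]])
    n_pred = cut_after + 1.0
    tp = cum_pos
    fp = n_pred - tp
    fn = n_pos - tp
    tn = n_neg - fp
    sn = tp / n_pos
    sp = tn / n_neg
    f1 = np.where(2 * tp + fp + fn > 0, 2 * tp / (2 * tp + fp + fn), 0.0)
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    mcc = np.where(denom > 0, (tp * tn - fn * fp) / np.sqrt(np.maximum(denom, 1)), 0.0)

    out: dict = {
        "MCCmax": float(mcc.max()),
        "F1max": float(f1.max()),
        "MCCmax_threshold": float(thresholds[int(mcc.argmax())]),
        "F1max_threshold": float(thresholds[int(f1.argmax())]),
        "sn_at_sp": {},
        "flags": [],
    }
    for target in sp_targets:
        ok = sp >= target
        if not ok.any():
            out["sn_at_sp"][target] = None
            out["flags"].append(f"SP_{target}_unreachable")
            continue
        best = np.lexsort((sp[ok], sn[ok]))[-1]  # max SN, ties -> higher SP
        idx = np.where(ok)[0][best]
        out["sn_at_sp"][target] = float(sn[idx])
        out["sn_at_sp_thresholds"] = out.get("sn_at_sp_thresholds", {})
        out["sn_at_sp_thresholds"][target] = float(thresholds[idx])
    return out


def curves_to_tsv(curves: CurveSet, path) -> None:
    """Write the four curves as a flat TSV of (curve, x, y) points."""
    with open(path, "w") as fh:
        fh.write("curve\tx\ty\n")
        for name, (x, y) in (("roc", curves.roc), ("pr", curves.pr),
                             ("cp", curves.cp), ("op", curves.op)):
            for xi, yi in zip(x, y):
                fh.write(f"{name}\t{xi:.6g}\t{yi:.6g}\n")


# ---------------------------------------------------------------------------
# Bootstrap significance


def _default_metrics() -> dict:
    return {
        "AUROC": lambda s, y: float(roc_auc_score((_codes(y) == CARB).astype(int), s)),
    }


def bootstrap_significance(scores_a, scores_b, labels, n_reps: int = 10,
                           frac: float = 0.5, seed: int = 0,
                           metrics: dict | None = None) -> dict:
    """Stratified-subsample comparison of two predictors on shared examples.

    Each replicate draws ``frac`` of every class independently (without
    replacement), computes each metric for both score vectors, then tests
    the two samples: Anderson–Darling at the 5% level decides normality —
    if either sample is non-normal the Wilcoxon rank-sum test is used,
    otherwise Student's t-test.  Significance is declared at p < 0.001.
    """
    if n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2")
    y = _codes(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise EvaluationError("score vectors and labels must align")
    metrics = metrics or _default_metrics()
    rng = np.random.default_rng(seed)
    per_metric: dict[str, tuple[list, list]] = {m: ([], []) for m in metrics}
    for _ in range(n_reps):
        idx = []
        for cls in np.unique(y):
            members = np.where(y == cls)[0]
            k = max(1, int(round(frac * len(members))))
            idx.append(rng.choice(members, size=k, replace=False))
        idx = np.concatenate(idx)
        for name, fn in metrics.items():
            per_metric[name][0].append(fn(a[idx], y[idx]))
            per_metric[name][1].append(fn(b[idx], y[idx]))
    report = {}
    for name, (va, vb) in per_metric.items():
        va, vb = np.array(va), np.array(vb)
        entry = {
            "mean_a": float(va.mean()), "sd_a": float(va.std(ddof=1)),
            "mean_b": float(vb.mean()), "sd_b": float(vb.std(ddof=1)),
        }
        if np.allclose(va, vb):
            entry.update(p_value=1.0, test="identical", significant=False)
        else:
            normal = all(_is_normal(v) for v in (va, vb))
            if normal:
                stat, p = stats.ttest_ind(va, vb)
                entry["test"] = "t-test"
            else:
                stat, p = stats.ranksums(va, vb)
                entry["test"] = "rank-sum"
            entry["p_value"] = float(p)
            entry["significant"] = bool(p < 0.001)
        report[name] = entry
    return report


def _is_normal(sample: np.ndarray, level: float = 0.05) -> bool:
    """Anderson–Darling normality check at the given significance level."""
    if np.std(sample) < 1e-12:
        return True  # degenerate; AD undefined, treat as trivially normal
    res = stats.anderson(sample, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float) / 100.0
    crit = res.critical_values[np.argmin(np.abs(levels - level))]
    return res.statistic < crit


# ---------------------------------------------------------------------------
# Full report


def evaluate_predictions(scores, labels, threshold: float | None = None,
                         sp_targets: tuple[float, ...] = (0.95, 0.90),
                         fpr_cutoffs: tuple[float, ...] = (0.05, 0.10)) -> dict:
    """Assemble the full evaluation report for one score vector."""
    y = _codes(labels)
    s = np.asarray(scores, dtype=float)
    curves, areas = curves_and_areas(s, y)
    report = dict(areas)
    optima = threshold_optima(s, y, sp_targets)
    report.update({"MCCmax": optima["MCCmax"], "F1max": optima["F1max"]})
    report["sn_at_sp"] = optima["sn_at_sp"]
    report["flags"] = list(curves.flags) + optima["flags"]
    for c in fpr_cutoffs:
        aulc, ratio = aulc_ratio(s, y, c)
        report[f"AULC@{c}"] = aulc
        report[f"AULCratio@{c}"] = ratio
    thr_map = optima.get("sn_at_sp_thresholds", {})
    report["rates_at_sp"] = {}
    for target in sp_targets:
        if target in thr_map:
            rates = cross_over_rates(s, y, thr_map[target])
            report["rates_at_sp"][target] = rates
    if threshold is not None:
        cm = confusion_metrics(confusion_counts(s, y, threshold))
        report["at_threshold"] = {"threshold": threshold, **cm,
                                  **cross_over_rates(s, y, threshold)}
    return report
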