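"""Desk-scale synthetic experiments probing the method's design claims.

These harnesses generate confusable synthetic data — a shared motif
vocabulary between carbonylation and ligand classes plus a distinct
ligand compositional bias — train scaled-down networks, and measure
cross-prediction on held-out data.  They demonstrate *directions* the
design aims at (a larger ligand-error weight β lowers the cross-prediction
area; transferring a pretrained frozen ligand module does not hurt it)
rather than any particular benchmark value.

Experiment conditions are chosen once so that the scaled-down model
reliably learns above-chance carbonylation signal — the comparison is only
meaningful for models that learn at all: 60 proteins per replicate
(~1700 pooled K/P/R/T segments), enriched positives (5% carbonylation /
10% ligand), dense motif planting (0.9) with heavy vocabulary sharing
(0.5), a 16-dim three-layer attention stack, and 10 epochs at batch 64
with learning rate 0.003 (the shortened schedule uses a larger step than
the production default to reach a trained model in few passes).  The
train-validation AUROC gap guard is widened to 0.30 here: with a handful
of positive validation examples the AUROC standard error is far above the
0.03 production guard, which would reject nearly every epoch.
"""

from __future__ import annotations

import numpy as np

from .metrics import curves_and_areas
from .pipeline import synthetic_feature_set
from .simulate import SimulationConfig
from .training import CarbonylationSiteClassifier

__all__ = ["CONFUSABLE_OVERRIDES", "SMALL_NET_PARAMS",
           "pooled_synthetic_set", "cross_suppression_experiment"]

#: Generator overrides producing strongly confusable, learnable data.
CONFUSABLE_OVERRIDES = dict(
    class_props=(0.05, 0.10, 0.85), plant_prob=0.9,
    shared_motif_prob=0.5, aromatic_bias=3,
)

#: Scaled-down architecture/training settings used by the desk experiments.
SMALL_NET_PARAMS = dict(
    window_size=13, model_dim=16, n_heads=2, conv_channels=(4, 8),
    fusion_widths=(64, 32, 8), embedding_dim=32, batch_size=64,
    learning_rate=0.003, max_epochs=10, pretrain_epochs=8, patience=10,
    auroc_gap_limit=0.30,
)

HELDOUT_SEED_OFFSET = 500


def pooled_synthetic_set(seed: int, n_proteins: int = 60,
                         length_range: tuple[int, int] = (100, 200),
                         window_size: int = 13,
                         overrides: dict | None = None):
    """One synthetic dataset with segments of all four residue types pooled.

    Pooling K/P/R/T keeps the configured class proportions while giving the
    scaled-down trainer enough positive examples per replicate.
    """
    cfg = SimulationConfig(n_proteins=n_proteins, length_range=length_range,
                           seed=seed,
                           **(CONFUSABLE_OVERRIDES if overrides is None
                              else overrides))
    Xs, ys = [], []
    for rt in "KPRT":
        _, X, y = synthetic_feature_set(cfg, rt, window_size)
        Xs.append(X)
        ys.append(y)
    X = {k: np.concatenate([x[k] for x in Xs])
         for k in ("physchem", "pssm", "embedding")}
    return X, np.concatenate(ys)


def cross_suppression_experiment(n_seeds: int = 5, base_seed: int = 0,
                                 n_proteins: int = 60,
                                 beta_high: float = 12.0) -> dict:
    """Held-out AUCPC under three configurations, per seed and averaged.

    Configurations: the full recipe (transfer + β = ``beta_high``), the
    same without the ligand-error term (β = 0), and the full loss without
    transfer (LISPM trained jointly, not pretrained/frozen).  Lower AUCPC
    means fewer cross-predictions.
    """
    results: dict[str, list[float]] = {"beta_high": [], "beta_zero": [],
                                       "no_transfer": []}
    configs = {
        "beta_high": dict(beta=beta_high, transfer=True),
        "beta_zero": dict(beta=0.0, transfer=True),
        "no_transfer": dict(beta=beta_high, transfer=False),
    }
    for i in range(n_seeds):
        seed = base_seed + i
        X, y = pooled_synthetic_set(seed, n_proteins=n_proteins)
        X_held, y_held = pooled_synthetic_set(seed + HELDOUT_SEED_OFFSET,
                                              n_proteins=n_proteins)
        for name, kw in configs.items():
            clf = CarbonylationSiteClassifier(
                seed=seed, alpha=1.0, r=2.0, **SMALL_NET_PARAMS, **kw)
            clf.fit(X, y)
            _, areas = curves_and_areas(clf.decision_function(X_held), y_held)
            results[name].append(areas["AUCPC"])
    return {
        "per_seed": results,
        "mean": {k: float(np.mean(v)) for k, v in results.items()},
    }
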