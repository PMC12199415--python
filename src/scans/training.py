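"""Training protocol: LISPM pretraining, transfer/freeze, fused training,
model selection, and the window-size and loss-parameter search harnesses.

The protocol has two phases.  First the ligand interaction-sites module
(LISPM) is pretrained with binary cross-entropy on a ligand-vs-rest
relabeling of the training set (carbonylation sites count as negatives).
Its parameters are then frozen — "transferred" — and the carbonylation
module, embedding reducer and fusion head are trained under the customized
focal loss.  In both phases the selected checkpoint maximizes validation
AUROC subject to an overfitting guard: the train-validation AUROC gap of
the selected epoch may not exceed 3 percentage points (0.03).

Optimization uses Adam with learning rate 0.001 and batch size 256.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score

from . import nn
from .errors import ConfigurationError, TrainingError
from .losses import LossParams, bce_loss_tensor, custom_loss_tensor, l2_loss_tensor
from .network import NetworkConfig, ScansNetwork

__all__ = [
    "TrainConfig",
    "pretrain_lispm",
    "train_scans",
    "CarbonylationSiteClassifier",
    "window_search",
    "loss_grid_search",
    "select_loss_params",
    "save_checkpoint",
    "load_checkpoint",
]

CARB, LIGAND = 0, 1
CHECKPOINT_VERSION = 1
EVAL_CAP = 1500  # negatives kept in the epoch-monitoring subsample


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    auroc_gap_limit: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 0:
            raise ConfigurationError(f"invalid training configuration: {self}")


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _auroc(net: ScansNetwork, data: dict, mode: str, positive_mask: np.ndarray,
           batch_size: int = 1024) -> float:
    scores = predict_scores(net, data, mode=mode, batch_size=batch_size)
    return float(roc_auc_score(positive_mask.astype(int), scores))


def predict_scores(net: ScansNetwork, data: dict, mode: str = "fused",
                   batch_size: int = 1024) -> np.ndarray:
    """Deterministic propensities for a featurized dataset."""
    n = data["labels"].shape[0]
    out = np.empty(n)
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        out[sl] = net.predict_proba(data["physchem"][sl], data["pssm"][sl],
                                    data["embedding"][sl], mode=mode)
    return out


def _run_epochs(net: ScansNetwork, optimizer: nn.Adam, loss_fn, train: dict,
                validation: dict, positive_of, mode: str, config: TrainConfig,
                state_keys: str | None = None):
    """Generic epoch loop with AUROC-gap-guarded checkpoint selection.

    ``positive_of(labels)`` defines the positive class for AUROC;
    ``loss_fn(p, labels)`` returns a scalar Tensor.  Returns (best state
    dict, history rows).  Raises TrainingError when no epoch satisfies the
    gap guard.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n = train["labels"].shape[0]
    # epoch-wise train AUROC on a capped stratified subsample (monitoring
    # only; does not affect gradients or the validation-based selection)
    if n > 2 * EVAL_CAP:
        sub_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 12]))
        pos = np.where(positive_of(train["labels"]))[0]
        rest = np.where(~positive_of(train["labels"]))[0]
        keep = min(len(rest), EVAL_CAP)
        monitor_idx = np.concatenate(
            [pos, sub_rng.choice(rest, size=keep, replace=False)])
        monitor = {k: v[monitor_idx] for k, v in train.items()}
    else:
        monitor = train
    history = []
    best = None  # (val_auroc, state)
    stall = 0
    for epoch in range(config.max_epochs):
        net.train()
        epoch_loss = 0.0
        n_batches = 0
        for idx in _batches(n, config.batch_size, rng):
            p = net.forward(train["physchem"][idx], train["pssm"][idx],
                            nn.Tensor(train["embedding"][idx]), mode=mode)
            loss = loss_fn(p, train["labels"][idx])
            net.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_auroc = _auroc(net, monitor, mode, positive_of(monitor["labels"]))
        val_auroc = _auroc(net, validation, mode, positive_of(validation["labels"]))
        gap = abs(train_auroc - val_auroc)
        admissible = gap <= config.auroc_gap_limit
        history.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
                        "train_auroc": train_auroc, "val_auroc": val_auroc,
                        "gap": gap, "admissible": admissible})
        if admissible and (best is None or val_auroc > best[0]):
            best = (val_auroc, net.state_dict())
            stall = 0
        else:
            stall += 1
            if stall >= config.patience and best is not None:
                break
    if config.max_epochs == 0:
        return net.state_dict(), history
    if best is None:
        gaps = [round(h["gap"], 4) for h in history]
        raise TrainingError(
            f"no epoch satisfied the AUROC gap guard "
            f"(limit {config.auroc_gap_limit}); gap trajectory: {gaps}")
    return best[1], history


def pretrain_lispm(train: dict, validation: dict, net: ScansNetwork,
                   config: TrainConfig) -> list[dict]:
    """Pretrain the ligand module with BCE on ligand-vs-rest labels.

    Carbonylation sites are negatives here.  The best-validation-AUROC
    checkpoint within the 3% train-validation gap is restored into the
    network.  Returns the per-epoch history.
    """
    params = [p for p in net.lispm.parameters()]
    optimizer = nn.Adam(params, lr=config.learning_rate)
    state, history = _run_epochs(
        net, optimizer,
        loss_fn=lambda p, labels: bce_loss_tensor(p, labels == LIGAND),
        train=train, validation=validation,
        positive_of=lambda labels: labels == LIGAND,
        mode="lispm", config=config)
    net.load_state_dict(state)
    return history


def train_scans(train: dict, validation: dict, net: ScansNetwork,
                loss_params: LossParams, config: TrainConfig,
                transfer: bool = True, loss_variant: str = "custom") -> list[dict]:
    """Train the fused predictor under the customized focal loss.

    With ``transfer=True`` the LISPM must already be pretrained; its
    parameters are frozen and verified bit-identical afterwards.
    ``loss_variant`` admits the ablation alternatives ``"bce"`` and
    ``"l2"`` (carbonylation-vs-rest).
    """
    if transfer:
        net.lispm.freeze(True)
    frozen_before = {k: v for k, v in net.state_dict().items()
                     if k.startswith("lispm.")} if transfer else {}
    params = [p for p in net.parameters() if not p.frozen]
    optimizer = nn.Adam(params, lr=config.learning_rate)
    if loss_variant == "custom":
        loss_fn = lambda p, labels: custom_loss_tensor(p, labels, loss_params)
    elif loss_variant == "bce":
        loss_fn = lambda p, labels: bce_loss_tensor(p, labels == CARB)
    elif loss_variant == "l2":
        loss_fn = lambda p, labels: l2_loss_tensor(p, labels == CARB)
    else:
        raise ConfigurationError(f"unknown loss variant {loss_variant!r}")
    state, history = _run_epochs(
        net, optimizer, loss_fn=loss_fn, train=train, validation=validation,
        positive_of=lambda labels: labels == CARB,
        mode="fused", config=config)
    if config.max_epochs > 0:
        net.load_state_dict(state)
    if transfer:
        after = net.state_dict()
        for k, v in frozen_before.items():
            if not np.array_equal(after[k], v):
                raise TrainingError(f"frozen LISPM parameter {k} changed")
    return history


# ---------------------------------------------------------------------------
# Estimator


class CarbonylationSiteClassifier(BaseEstimator):
    """Sklearn-style estimator for the full two-module predictor.

    ``fit(X, y)`` takes featurized channels — ``X`` is a dict with keys
    ``physchem`` (N, 2w+1, 10), ``pssm`` (N, 2w+1, 20) and ``embedding``
    (N, d) — and three-way integer labels ``y`` (0 carbonylation, 1 ligand,
    2 nonfunctional).  An internal stratified split provides the validation
    set for checkpoint selection.  ``decision_function`` returns the
    carbonylation propensity; ``predict`` thresholds it at the SP-anchored
    operating point calibrated on the validation split.

    Ablation variants (mirroring the interpretability analysis): disable
    ``transfer`` to skip LISPM pretraining+freezing, set ``loss_variant``
    to ``"bce"``/``"l2"``, or ``attention="fcnn"`` to replace the TRF/CNN
    attention blocks with plain dense networks.
    """

    def __init__(self, window_size: int = 13, model_dim: int = 64,
                 n_heads: int = 4, n_trf_layers: int = 3,
                 conv_channels: tuple[int, int] = (16, 32),
                 dropout: float = 0.5,
                 fusion_widths: tuple[int, int, int] = (256, 64, 16),
                 embedding_dim: int = 32,
                 r: float = 2.0, alpha: float = 1.0, beta: float = 1.0,
                 learning_rate: float = 0.001, batch_size: int = 256,
                 max_epochs: int = 100, pretrain_epochs: int | None = None,
                 patience: int = 10, auroc_gap_limit: float = 0.03,
                 transfer: bool = True, loss_variant: str = "custom",
                 attention: str = "attention",
                 validation_fraction: float = 0.2,
                 sp_anchor: float = 0.95, seed: int = 0):
        self.window_size = window_size
        self.model_dim = model_dim
        self.n_heads = n_heads
        self.n_trf_layers = n_trf_layers
        self.conv_channels = conv_channels
        self.dropout = dropout
        self.fusion_widths = fusion_widths
        self.embedding_dim = embedding_dim
        self.r = r
        self.alpha = alpha
        self.beta = beta
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.pretrain_epochs = pretrain_epochs
        self.patience = patience
        self.auroc_gap_limit = auroc_gap_limit
        self.transfer = transfer
        self.loss_variant = loss_variant
        self.attention = attention
        self.validation_fraction = validation_fraction
        self.sp_anchor = sp_anchor
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _network_config(self) -> NetworkConfig:
        return NetworkConfig(
            window_size=self.window_size, model_dim=self.model_dim,
            n_heads=self.n_heads, n_trf_layers=self.n_trf_layers,
            conv_channels=tuple(self.conv_channels), dropout=self.dropout,
            fusion_widths=tuple(self.fusion_widths),
            embedding_dim=self.embedding_dim)

    def _train_config(self, max_epochs=None) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs if max_epochs is None else max_epochs,
            patience=self.patience, auroc_gap_limit=self.auroc_gap_limit,
            seed=self.seed)

    @staticmethod
    def _check_X(X) -> dict:
        for key in ("physchem", "pssm", "embedding"):
            if key not in X:
                raise ConfigurationError(f"X must contain channel {key!r}")
        return X

    def _split(self, X: dict, y: np.ndarray):
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 21]))
        val_idx, train_idx = [], []
        for cls in np.unique(y):
            members = np.where(y == cls)[0]
            members = members[rng.permutation(len(members))]
            k = max(1, int(round(self.validation_fraction * len(members))))
            val_idx.append(members[:k])
            train_idx.append(members[k:])
        train_idx = np.concatenate(train_idx)
        val_idx = np.concatenate(val_idx)

        def take(idx):
            return {"physchem": X["physchem"][idx], "pssm": X["pssm"][idx],
                    "embedding": X["embedding"][idx], "labels": y[idx]}

        return take(train_idx), take(val_idx)

    # -- estimator API ------------------------------------------------------
    def fit(self, X, y) -> "CarbonylationSiteClassifier":
        X = self._check_X(X)
        y = np.asarray(y, dtype=int)
        if X["physchem"].shape[1] != self.window_size:
            raise ConfigurationError(
                f"feature window {X['physchem'].shape[1]} != configured "
                f"window_size {self.window_size}")
        if self.attention == "fcnn":
            from .network_fcnn import FcnnNetwork
            net = FcnnNetwork(self._network_config(), seed=self.seed)
        elif self.attention == "attention":
            net = ScansNetwork(self._network_config(), seed=self.seed)
        else:
            raise ConfigurationError(f"unknown attention variant {self.attention!r}")
        train, validation = self._split(X, y)
        if self.transfer:
            pre_cfg = dataclasses.replace(
                self._train_config(),
                max_epochs=(self.pretrain_epochs if self.pretrain_epochs
                            is not None else self.max_epochs))
            self.pretrain_history_ = pretrain_lispm(train, validation, net, pre_cfg)
        else:
            self.pretrain_history_ = []
        self.history_ = train_scans(
            train, validation, net,
            LossParams(r=self.r, alpha=self.alpha, beta=self.beta),
            self._train_config(), transfer=self.transfer,
            loss_variant=self.loss_variant)
        self.network_ = net
        self.classes_ = np.array([0, 1])
        # SP-anchored operating threshold calibrated on the validation split
        val_scores = predict_scores(net, validation)
        neg = val_scores[validation["labels"] != CARB]
        self.threshold_ = (float(np.quantile(neg, self.sp_anchor))
                           if len(neg) else 0.5)
        self.validation_auroc_ = (max((h["val_auroc"] for h in self.history_
                                       if h["admissible"]), default=None)
                                  if self.history_ else None)
        return self

    def decision_function(self, X) -> np.ndarray:
        self._require_fitted()
        X = self._check_X(X)
        data = {**X, "labels": np.zeros(X["physchem"].shape[0], dtype=int)}
        return predict_scores(self.network_, data)

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.threshold_).astype(int)

    def _require_fitted(self):
        if not hasattr(self, "network_"):
            raise ConfigurationError("estimator is not fitted")


# ---------------------------------------------------------------------------
# Hyperparameter-search harnesses

DEFAULT_WINDOW_CANDIDATES = (5, 7, 9, 11, 13, 15, 17, 19, 21)


def window_search(featurize, y_by_window=None,
                  candidate_sizes=DEFAULT_WINDOW_CANDIDATES,
                  estimator_params: dict | None = None,
                  eval_split=None) -> tuple[list[dict], int]:
    """Train one model per candidate window size and tabulate AUROC/AUCPC.

    ``featurize(window_size)`` must return ``(X, y)`` for that window (the
    stored 27-residue segments are cropped, not re-extracted).  Selection
    maximizes validation AUROC among sizes whose fit satisfied the gap
    guard.  Returns (table, selected window).
    """
    from .metrics import curves_and_areas
    if any(w % 2 == 0 for w in candidate_sizes):
        raise ConfigurationError("candidate window sizes must be odd")
    table = []
    for w in candidate_sizes:
        X, y = featurize(w)
        clf = CarbonylationSiteClassifier(**{**(estimator_params or {}),
                                             "window_size": w})
        clf.fit(X, y)
        if eval_split is not None:
            X_ev, y_ev = eval_split(w)
        else:
            X_ev, y_ev = X, y
        scores = clf.decision_function(X_ev)
        _, areas = curves_and_areas(scores, y_ev)
        table.append({"window": w, "AUROC": areas["AUROC"],
                      "AUCPC": areas["AUCPC"],
                      "val_auroc": clf.validation_auroc_})
    admissible = [row for row in table if row["val_auroc"] is not None]
    pool = admissible or table
    selected = max(pool, key=lambda r: (r["AUROC"], -r["window"]))["window"]
    return table, selected


def select_loss_params(table: list[dict], band: float = 0.02) -> dict:
    """Apply the printed selection rule to a (α, β, AUROC, AUCPC) table.

    Admissible cells have AUCPC within ``band`` (absolute) of the grid
    minimum AUCPC; among them the maximum-AUROC cell wins.  Ties break
    toward lower AUCPC, then lower (α, β), so the pick is independent of
    enumeration order.
    """
    if not table:
        raise ConfigurationError("empty grid")
    min_aucpc = min(row["AUCPC"] for row in table)
    admissible = [row for row in table if row["AUCPC"] <= min_aucpc + band]
    return min(admissible,
               key=lambda r: (-r["AUROC"], r["AUCPC"], r["alpha"], r["beta"]))


def loss_grid_search(X, y, alpha_grid, beta_grid,
                     estimator_params: dict | None = None,
                     eval_data=None, band: float = 0.02) -> tuple[list[dict], dict]:
    """Grid search over (α, β); returns the heatmap table and selected cell."""
    from .metrics import curves_and_areas
    if not alpha_grid or not beta_grid:
        raise ConfigurationError("grids must be nonempty")
    table = []
    for a in alpha_grid:
        for b in beta_grid:
            clf = CarbonylationSiteClassifier(**{**(estimator_params or {}),
                                                 "alpha": a, "beta": b})
            clf.fit(X, y)
            X_ev, y_ev = eval_data if eval_data is not None else (X, y)
            scores = clf.decision_function(X_ev)
            _, areas = curves_and_areas(scores, y_ev)
            table.append({"alpha": a, "beta": b, "AUROC": areas["AUROC"],
                          "AUCPC": areas["AUCPC"]})
    return table, select_loss_params(table, band)


# ---------------------------------------------------------------------------
# Checkpointing


def save_checkpoint(path, net: ScansNetwork, extra: dict | None = None) -> None:
    """Single-file checkpoint: parameters + embedded config (versioned)."""
    meta = {"version": CHECKPOINT_VERSION,
            "config": dataclasses.asdict(net.config),
            "extra": extra or {}}
    arrays = {f"param::{k}": v for k, v in net.state_dict().items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[ScansNetwork, dict]:
    with np.load(path, allow_pickle=False) as zf:
        meta = json.loads(str(zf["meta"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {meta['version']}")
        cfg_dict = meta["config"]
        for key in ("conv_channels", "fusion_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = ScansNetwork(NetworkConfig(**cfg_dict))
        state = {k.split("::", 1)[1]: zf[k] for k in zf.files if k.startswith("param::")}
    net.load_state_dict(state)
    return net, meta["extra"]
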