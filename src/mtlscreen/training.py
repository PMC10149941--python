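"""Training protocol: paired no-shuffle batching, Adam with
reduce-LR-on-plateau, early stopping, best-checkpoint restoration, and the
split-ensemble with probability averaging.

Rows of an aligned pair dataset move as units and batches are formed in
stored order, never shuffled: shuffling the two task streams independently
would break the class alignment that soft parameter sharing relies on.  The
plateau logic is a pure function of the validation-loss sequence
(:class:`PlateauController`), so the stopping/LR rules are unit-testable
against scripted traces.  Validation loss for model selection is the full
summed objective including the soft-share MSE term (configurable).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mtl_model import (
    LossValue,
    ModelConfig,
    MTLNetwork,
    SingleTaskNetwork,
    categorical_cross_entropy,
    mtl_loss,
)
from .nn import Adam


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 10
    early_stop_patience: int = 3
    lr_reduce_factor: float = 0.1
    lr_reduce_patience: int = 2
    min_lr: float = 1e-8
    min_delta: float = 1e-6
    seed: int = 0
    select_on_total_loss: bool = True  # include soft-share MSE in val selection

    def __post_init__(self) -> None:
        if not (0.0 < self.lr_reduce_factor < 1.0):
            raise ValueError("lr_reduce_factor must be in (0, 1)")
        if self.min_lr >= self.learning_rate:
            raise ValueError("min_lr must be below learning_rate")
        if min(self.early_stop_patience, self.lr_reduce_patience) < 1:
            raise ValueError("patience values must be >= 1")


class PlateauController:
    """Early-stopping + reduce-LR-on-plateau as a pure loss-trace function.

    "Improvement" means a strict decrease of at least ``min_delta`` below the
    best loss seen so far.  Both patience counters reference the same best
    value and operate independently: the learning rate is multiplied by
    ``factor`` (floored at ``min_lr``) after ``lr_patience`` consecutive
    non-improving epochs, and training stops after ``early_patience`` of them.
    """

    def __init__(
        self,
        early_patience: int = 3,
        lr_patience: int = 2,
        factor: float = 0.1,
        min_lr: float = 1e-8,
        min_delta: float = 1e-6,
    ):
        self.early_patience = early_patience
        self.lr_patience = lr_patience
        self.factor = factor
        self.min_lr = min_lr
        self.min_delta = min_delta
        self.best = np.inf
        self._bad_stop = 0
        self._bad_lr = 0

    def update(self, val_loss: float, lr: float) -> tuple[bool, float, bool]:
        """Feed one epoch's validation loss; returns (improved, new_lr, stop)."""
        improved = val_loss < self.best - self.min_delta
        if improved:
            self.best = val_loss
            self._bad_stop = 0
            self._bad_lr = 0
            return True, lr, False
        self._bad_stop += 1
        self._bad_lr += 1
        if self._bad_lr >= self.lr_patience:
            lr = max(lr * self.factor, self.min_lr)
            self._bad_lr = 0
        return False, lr, self._bad_stop >= self.early_patience


@dataclass
class EncodedPairs:
    """Row-aligned encoded inputs for the two tasks (labels agree per row for
    training data; at inference the two label vectors may differ)."""

    X_s: np.ndarray
    X_m: np.ndarray
    y_s: np.ndarray
    y_m: np.ndarray
    aux_s: Optional[np.ndarray] = None
    aux_m: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = len(self.X_s)
        for arr in (self.X_m, self.y_s, self.y_m):
            if len(arr) != n:
                raise ValueError("all arrays must have the same row count")

    def __len__(self) -> int:
        return len(self.X_s)

    def subset(self, idx: np.ndarray) -> "EncodedPairs":
        return EncodedPairs(
            X_s=self.X_s[idx],
            X_m=self.X_m[idx],
            y_s=self.y_s[idx],
            y_m=self.y_m[idx],
            aux_s=None if self.aux_s is None else self.aux_s[idx],
            aux_m=None if self.aux_m is None else self.aux_m[idx],
        )


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_loss_components: list[dict] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)
    batch_hashes: list[str] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0


def _fixed_batches(n: int, batch_size: int) -> list[np.ndarray]:
    """Contiguous batches in stored order; identical every epoch (no shuffle)."""
    return [np.arange(i, min(i + batch_size, n)) for i in range(0, n, batch_size)]


def _hash_batches(batches: Sequence[np.ndarray]) -> str:
    h = hashlib.sha1()
    for b in batches:
        h.update(b.tobytes())
    return h.hexdigest()


def _val_loss_mtl(net: MTLNetwork, val: EncodedPairs, cfg: TrainConfig) -> LossValue:
    p_s, p_m, v_s, v_m = net.forward(
        val.X_s, val.X_m, val.aux_s, val.aux_m, train=False
    )
    loss = mtl_loss(val.y_s, p_s, val.y_m, p_m, v_s, v_m, net.config.soft_share_weight)
    if not cfg.select_on_total_loss:
        loss = replace_total(loss)
    return loss


def replace_total(loss: LossValue) -> LossValue:
    return LossValue(
        total=loss.cce_suicide + loss.cce_disorder,
        cce_suicide=loss.cce_suicide,
        cce_disorder=loss.cce_disorder,
        soft_share_mse=loss.soft_share_mse,
    )


def train_mtl(
    network: MTLNetwork,
    split: tuple[EncodedPairs, EncodedPairs],
    cfg: TrainConfig,
) -> tuple[MTLNetwork, TrainHistory]:
    """Train one multi-task network on a (train, validation) split.

    Halts at ``max_epochs`` or when validation loss has not improved for
    ``early_stop_patience`` epochs; the learning rate decays by
    ``lr_reduce_factor`` after ``lr_reduce_patience`` non-improving epochs,
    floored at ``min_lr``.  Weights are restored to the best-validation-loss
    epoch before returning.
    """
    train, val = split
    if len(train) == 0 or len(val) == 0:
        raise ValueError("train and validation splits must be nonempty")
    opt = Adam(network.params, lr=cfg.learning_rate)
    ctrl = PlateauController(
        cfg.early_stop_patience, cfg.lr_reduce_patience,
        cfg.lr_reduce_factor, cfg.min_lr, cfg.min_delta,
    )
    batches = _fixed_batches(len(train), cfg.batch_size)
    history = TrainHistory()
    best_weights = network.get_weights()
    for epoch in range(1, cfg.max_epochs + 1):
        epoch_losses = []
        for b in batches:
            opt.zero_grad()
            network.forward(
                train.X_s[b], train.X_m[b],
                None if train.aux_s is None else train.aux_s[b],
                None if train.aux_m is None else train.aux_m[b],
                train=True,
            )
            loss = network.backward(train.y_s[b], train.y_m[b])
            opt.step()
            epoch_losses.append(loss.total)
        vloss = _val_loss_mtl(network, val, cfg)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(vloss.total)
        history.val_loss_components.append(vars(vloss))
        history.lr_trace.append(opt.lr)
        history.batch_hashes.append(_hash_batches(batches))
        improved, new_lr, stop = ctrl.update(vloss.total, opt.lr)
        if improved:
            best_weights = network.get_weights()
            history.best_epoch = epoch
        opt.lr = new_lr
        history.stopped_epoch = epoch
        if stop:
            break
    network.set_weights(best_weights)
    return network, history


def train_single_task(
    network: SingleTaskNetwork,
    split: tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[SingleTaskNetwork, TrainHistory]:
    """Same protocol as :func:`train_mtl` without pairing or soft-share loss."""
    (X_tr, y_tr), (X_va, y_va) = split
    if len(X_tr) == 0 or len(X_va) == 0:
        raise ValueError("train and validation splits must be nonempty")
    opt = Adam(network.params, lr=cfg.learning_rate)
    ctrl = PlateauController(
        cfg.early_stop_patience, cfg.lr_reduce_patience,
        cfg.lr_reduce_factor, cfg.min_lr, cfg.min_delta,
    )
    batches = _fixed_batches(len(X_tr), cfg.batch_size)
    history = TrainHistory()
    best_weights = network.get_weights()
    for epoch in range(1, cfg.max_epochs + 1):
        epoch_losses = []
        for b in batches:
            opt.zero_grad()
            network.forward(X_tr[b], train=True)
            epoch_losses.append(network.backward(y_tr[b]))
            opt.step()
        p_va = network.forward(X_va, train=False)
        vloss = categorical_cross_entropy(y_va, p_va)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(vloss)
        history.lr_trace.append(opt.lr)
        history.batch_hashes.append(_hash_batches(batches))
        improved, new_lr, stop = ctrl.update(vloss, opt.lr)
        if improved:
            best_weights = network.get_weights()
            history.best_epoch = epoch
        opt.lr = new_lr
        history.stopped_epoch = epoch
        if stop:
            break
    network.set_weights(best_weights)
    return network, history


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """Deterministic per-model seeds below 2**31."""
    states = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in states]


def train_ensemble(
    model_config: ModelConfig,
    data: EncodedPairs,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[list[MTLNetwork], list[TrainHistory]]:
    """One independently initialized multi-task model per stratified split."""
    if not splits:
        raise ValueError("at least one split is required")
    models, histories = [], []
    for seed, (tr, va) in zip(derive_seeds(cfg.seed, len(splits)), splits):
        net = MTLNetwork(model_config, seed=seed)
        net, hist = train_mtl(net, (data.subset(tr), data.subset(va)), cfg)
        models.append(net)
        histories.append(hist)
    return models, histories


def train_single_task_ensemble(
    model_config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    splits: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[list[SingleTaskNetwork], list[TrainHistory]]:
    """Per-split single-task baselines trained with the same protocol."""
    if not splits:
        raise ValueError("at least one split is required")
    models, histories = [], []
    for seed, (tr, va) in zip(derive_seeds(cfg.seed, len(splits)), splits):
        net = SingleTaskNetwork(model_config, seed=seed)
        net, hist = train_single_task(net, ((X[tr], y[tr]), (X[va], y[va])), cfg)
        models.append(net)
        histories.append(hist)
    return models, histories


def predict_ensemble(
    models: Sequence[MTLNetwork],
    X_s: np.ndarray,
    X_m: np.ndarray,
    aux_s: np.ndarray | None = None,
    aux_m: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Average per-task class probabilities over models, then argmax.

    Averaging is elementwise, so the averaged rows still sum to one; the
    ensemble smooths out split-to-split variance from the stochastic training.
    """
    if not models:
        raise ValueError("no models given")
    cfg0 = models[0].config
    if any(m.config != cfg0 for m in models):
        raise ValueError("all ensemble members must share one ModelConfig")
    acc_s = acc_m = None
    for m in models:
        p_s, p_m, _, _ = m.forward(X_s, X_m, aux_s, aux_m, train=False)
        acc_s = p_s if acc_s is None else acc_s + p_s
        acc_m = p_m if acc_m is None else acc_m + p_m
    p_s = acc_s / len(models)
    p_m = acc_m / len(models)
    return {
        "probs_suicide": p_s,
        "probs_disorder": p_m,
        "labels_suicide": p_s.argmax(axis=1),
        "labels_disorder": p_m.argmax(axis=1),
    }


def predict_single_task_ensemble(
    models: Sequence[SingleTaskNetwork], X: np.ndarray
) -> dict[str, np.ndarray]:
    if not models:
        raise ValueError("no models given")
    cfg0 = models[0].config
    if any(m.config != cfg0 for m in models):
        raise ValueError("all ensemble members must share one ModelConfig")
    acc = None
    for m in models:
        p = m.forward(X, train=False)
        acc = p if acc is None else acc + p
    p = acc / len(models)
    return {"probs": p, "labels": p.argmax(axis=1)}
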