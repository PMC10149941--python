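"""Dual-branch multi-channel CNN with soft and hard parameter sharing.

Two structurally identical branches — one per task (suicide-ideation side
"s", mental-disorder side "m") — each embed a user's token sequence, run it
through parallel 1-D convolution channels (kernel sizes 3 and 4, giving
3-gram and 4-gram feature detectors), globally max-pool each channel, apply
dropout and a per-channel dense layer, and concatenate the channel outputs
into a task representation vector (2 x 512 = 1024 wide at defaults).  An
optional auxiliary input (scaled lexicon-category features) passes through a
small dense layer whose output is appended to the task vector (1024 + 8 =
1032 at the 8-unit setting).

Parameter sharing is twofold:

* soft — the two task vectors of each aligned user pair are pulled together
  by a mean-squared-error penalty added to the loss;
* hard — the task vectors are concatenated into a shared representation
  (2048 features at defaults) that BOTH softmax heads read, so each task's
  head is optimized on features shaped by the other task.

The training objective is the sum of the two categorical cross-entropies and
the soft-share MSE (weight ``soft_share_weight``, default 1), plus small
L1/L2 penalties on convolution and dense kernels.

The single-task baseline is one branch without the per-channel dense layers:
embedding -> two conv channels -> global max pool -> dropout -> concatenation
-> softmax, trained with plain cross-entropy.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .nn import (
    ConvStack,
    DenseLayer,
    Param,
    apply_weight_penalty,
    get_weights,
    set_weights,
    softmax,
)

_LOG_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    vocab_size: int
    max_len: int
    embed_dim: int = 300
    n_channels: int = 2
    kernel_sizes: tuple[int, ...] = (3, 4)
    n_filters: int = 256
    dense_units: int = 512
    dropout_p: float = 0.5
    l1_factor: float = 1e-5
    l2_factor: float = 1e-5
    activation: str = "relu"
    leaky_alpha: float = 0.2
    aux_units: Optional[int] = None
    n_aux_features: Optional[int] = None
    n_classes: int = 2
    soft_share_weight: float = 1.0

    def __post_init__(self) -> None:
        if len(self.kernel_sizes) != self.n_channels:
            raise ValueError("kernel_sizes length must equal n_channels")
        if min(self.vocab_size, self.max_len, self.embed_dim, self.n_filters,
               self.dense_units, self.n_classes) < 1:
            raise ValueError("all dimensions must be positive")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        if self.max_len < max(self.kernel_sizes):
            raise ValueError(
                f"max_len {self.max_len} shorter than largest kernel {max(self.kernel_sizes)}"
            )
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.aux_units is not None and self.n_aux_features is None:
            raise ValueError("aux_units requires n_aux_features")

    @property
    def task_vector_width(self) -> int:
        w = self.n_channels * self.dense_units
        return w + (self.aux_units or 0)

    @property
    def shared_width(self) -> int:
        return 2 * self.task_vector_width


@dataclass
class LossValue:
    """Components of the summed multi-task loss: total = cce_s + cce_m + λ·mse."""

    total: float
    cce_suicide: float
    cce_disorder: float
    soft_share_mse: float


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 2:
        return y.astype(np.float64)
    out = np.zeros((y.shape[0], n_classes), dtype=np.float64)
    out[np.arange(y.shape[0]), y.astype(int)] = 1.0
    return out


def categorical_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean over the batch of -sum(y log p), log clipped at 1e-7."""
    y = _one_hot(y, p.shape[1])
    logp = np.log(np.clip(p, _LOG_EPS, 1.0))
    return float(-(y * logp).sum(axis=1).mean())


def mtl_loss(
    y_s: np.ndarray,
    p_s: np.ndarray,
    y_m: np.ndarray,
    p_m: np.ndarray,
    v_s: np.ndarray,
    v_m: np.ndarray,
    soft_share_weight: float = 1.0,
) -> LossValue:
    """Summed loss: both tasks' cross-entropies plus the soft-share MSE.

    ``soft_share_mse`` is the mean over the batch of the mean squared
    elementwise difference between the two aligned task vectors.
    """
    v_s = np.asarray(v_s, dtype=np.float64)
    v_m = np.asarray(v_m, dtype=np.float64)
    if v_s.shape != v_m.shape:
        raise ValueError(f"task-vector shape mismatch: {v_s.shape} vs {v_m.shape}")
    cce_s = categorical_cross_entropy(y_s, p_s)
    cce_m = categorical_cross_entropy(y_m, p_m)
    mse = float(np.mean(np.square(v_s - v_m)))
    return LossValue(
        total=cce_s + cce_m + soft_share_weight * mse,
        cce_suicide=cce_s,
        cce_disorder=cce_m,
        soft_share_mse=mse,
    )


class TaskBranch:
    """One task's subnetwork: embedding -> conv channels -> per-channel dense,
    with an optional auxiliary dense layer appended to the task vector."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        self.conv = ConvStack(
            vocab_size=config.vocab_size,
            embed_dim=config.embed_dim,
            kernel_sizes=config.kernel_sizes,
            n_filters=config.n_filters,
            dropout_p=config.dropout_p,
            activation=config.activation,
            leaky_alpha=config.leaky_alpha,
            rng=rng,
        )
        self.channel_dense = [
            DenseLayer(
                config.n_filters, config.dense_units, rng,
                activation=config.activation, leaky_alpha=config.leaky_alpha,
                regularized=True,
            )
            for _ in config.kernel_sizes
        ]
        self.aux_dense: DenseLayer | None = None
        if config.aux_units is not None:
            self.aux_dense = DenseLayer(
                config.n_aux_features, config.aux_units, rng,
                activation=config.activation, leaky_alpha=config.leaky_alpha,
                regularized=True,
            )

    @property
    def params(self) -> list[Param]:
        out = list(self.conv.params)
        for d in self.channel_dense:
            out.extend(d.params)
        if self.aux_dense is not None:
            out.extend(self.aux_dense.params)
        return out

    @property
    def width(self) -> int:
        return self.config.task_vector_width

    def forward(
        self,
        X: np.ndarray,
        aux: np.ndarray | None,
        train: bool,
        drop_rng: np.random.Generator | None,
    ) -> np.ndarray:
        if (aux is None) != (self.aux_dense is None):
            raise ValueError("auxiliary input presence must match the configured branch")
        pooled = self.conv.forward(X, train=train, drop_rng=drop_rng)
        parts = [d.forward(p) for d, p in zip(self.channel_dense, pooled)]
        if self.aux_dense is not None:
            parts.append(self.aux_dense.forward(np.asarray(aux, dtype=np.float32)))
        return np.concatenate(parts, axis=1)

    def backward(self, dv: np.ndarray) -> None:
        du = self.config.dense_units
        dpooled = [
            d.backward(dv[:, i * du : (i + 1) * du])
            for i, d in enumerate(self.channel_dense)
        ]
        if self.aux_dense is not None:
            self.aux_dense.backward(dv[:, len(self.channel_dense) * du :])
        self.conv.backward(dpooled)


class MTLNetwork:
    """The full two-task network: two branches, shared concatenated layer,
    two softmax heads reading the same shared vector."""

    def __init__(self, config: ModelConfig, seed: int = 0, tied_init: bool = False):
        self.config = config
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        kb_s, kb_m, kb_h, kb_drop = ss.spawn(4)
        if tied_init:
            kb_m = kb_s  # identical branch weights: soft-share MSE is 0 at step 0
        self.branch_suicide = TaskBranch(config, np.random.default_rng(kb_s))
        self.branch_disorder = TaskBranch(config, np.random.default_rng(kb_m))
        head_rng = np.random.default_rng(kb_h)
        self.head_suicide = DenseLayer(
            config.shared_width, config.n_classes, head_rng, activation=None, regularized=False
        )
        self.head_disorder = DenseLayer(
            config.shared_width, config.n_classes, head_rng, activation=None, regularized=False
        )
        self._drop_rng = np.random.default_rng(kb_drop)
        self._cache: dict | None = None

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[Param]:
        return (
            self.branch_suicide.params
            + self.branch_disorder.params
            + self.head_suicide.params
            + self.head_disorder.params
        )

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return get_weights(self.params)

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        set_weights(self.params, weights)

    # -- forward / backward -------------------------------------------------
    def forward(
        self,
        X_s: np.ndarray,
        X_m: np.ndarray,
        aux_s: np.ndarray | None = None,
        aux_m: np.ndarray | None = None,
        train: bool = False,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Returns (probs_suicide, probs_disorder, v_suicide, v_disorder)."""
        if X_s.shape[0] != X_m.shape[0]:
            raise ValueError("both tasks must be fed the same number of rows")
        v_s = self.branch_suicide.forward(X_s, aux_s, train, self._drop_rng)
        v_m = self.branch_disorder.forward(X_m, aux_m, train, self._drop_rng)
        shared = np.concatenate([v_s, v_m], axis=1)
        p_s = softmax(self.head_suicide.forward(shared))
        p_m = softmax(self.head_disorder.forward(shared))
        self._cache = {"v_s": v_s, "v_m": v_m, "p_s": p_s, "p_m": p_m}
        return p_s, p_m, v_s, v_m

    def backward(self, y_s: np.ndarray, y_m: np.ndarray) -> LossValue:
        """Backpropagate the summed loss for the cached forward pass."""
        c = self._cache
        if c is None:
            raise RuntimeError("forward must run (train=True) before backward")
        p_s, p_m, v_s, v_m = c["p_s"], c["p_m"], c["v_s"], c["v_m"]
        B = p_s.shape[0]
        lam = self.config.soft_share_weight
        loss = mtl_loss(y_s, p_s, y_m, p_m, v_s, v_m, lam)

        dlog_s = ((p_s - _one_hot(y_s, p_s.shape[1])) / B).astype(np.float32)
        dlog_m = ((p_m - _one_hot(y_m, p_m.shape[1])) / B).astype(np.float32)
        dshared = self.head_suicide.backward(dlog_s) + self.head_disorder.backward(dlog_m)
        w = self.config.task_vector_width
        dv_s = dshared[:, :w].copy()
        dv_m = dshared[:, w:].copy()
        ddiff = (2.0 * lam / (B * w)) * (v_s - v_m).astype(np.float32)
        dv_s += ddiff
        dv_m -= ddiff
        self.branch_suicide.backward(dv_s)
        self.branch_disorder.backward(dv_m)
        apply_weight_penalty(self.params, self.config.l1_factor, self.config.l2_factor)
        return loss

    # -- introspection / persistence ---------------------------------------
    def architecture_summary(self) -> list[dict]:
        cfg = self.config
        rows = [
            {"layer": "embedding (per branch)", "output_width": cfg.embed_dim},
            *[
                {"layer": f"conv1d k={k} (per branch/channel)", "output_width": cfg.n_filters}
                for k in cfg.kernel_sizes
            ],
            {"layer": "dense (per branch/channel)", "output_width": cfg.dense_units},
        ]
        if cfg.aux_units is not None:
            rows.append({"layer": "aux dense (per branch)", "output_width": cfg.aux_units})
        rows += [
            {"layer": "task vector (per branch)", "output_width": cfg.task_vector_width},
            {"layer": "shared representation", "output_width": cfg.shared_width},
            {"layer": "softmax head (per task)", "output_width": cfg.n_classes},
        ]
        return rows

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez_compressed(
            os.path.join(directory, "weights.npz"),
            **{f"p{i}": w for i, w in enumerate(self.get_weights())},
        )
        with open(os.path.join(directory, "config.json"), "w") as fh:
            json.dump({"model_config": asdict(self.config), "seed": self.seed,
                       "kind": "mtl"}, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "MTLNetwork":
        with open(os.path.join(directory, "config.json")) as fh:
            meta = json.load(fh)
        cfg_dict = meta["model_config"]
        cfg_dict["kernel_sizes"] = tuple(cfg_dict["kernel_sizes"])
        net = cls(ModelConfig(**cfg_dict), seed=meta["seed"])
        data = np.load(os.path.join(directory, "weights.npz"))
        net.set_weights([data[f"p{i}"] for i in range(len(data.files))])
        return net


class SingleTaskNetwork:
    """Single-task baseline: one multi-channel CNN feeding one softmax head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        kb_net, kb_drop = ss.spawn(2)
        rng = np.random.default_rng(kb_net)
        self.conv = ConvStack(
            vocab_size=config.vocab_size,
            embed_dim=config.embed_dim,
            kernel_sizes=config.kernel_sizes,
            n_filters=config.n_filters,
            dropout_p=config.dropout_p,
            activation=config.activation,
            leaky_alpha=config.leaky_alpha,
            rng=rng,
        )
        concat_width = config.n_channels * config.n_filters
        self.head = DenseLayer(
            concat_width, config.n_classes, rng, activation=None, regularized=False
        )
        self._drop_rng = np.random.default_rng(kb_drop)
        self._cache: dict | None = None

    @property
    def params(self) -> list[Param]:
        return self.conv.params + self.head.params

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return get_weights(self.params)

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        set_weights(self.params, weights)

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        pooled = self.conv.forward(X, train=train, drop_rng=self._drop_rng)
        concat = np.concatenate(pooled, axis=1)
        p = softmax(self.head.forward(concat))
        self._cache = {"p": p}
        return p

    def backward(self, y: np.ndarray) -> float:
        c = self._cache
        if c is None:
            raise RuntimeError("forward must run before backward")
        p = c["p"]
        B = p.shape[0]
        loss = categorical_cross_entropy(y, p)
        dlog = ((p - _one_hot(y, p.shape[1])) / B).astype(np.float32)
        dconcat = self.head.backward(dlog)
        F = self.config.n_filters
        self.conv.backward(
            [dconcat[:, i * F : (i + 1) * F] for i in range(self.config.n_channels)]
        )
        apply_weight_penalty(self.params, self.config.l1_factor, self.config.l2_factor)
        return loss


def build_task_branch(config: ModelConfig, seed: int = 0) -> TaskBranch:
    return TaskBranch(config, np.random.default_rng(np.random.SeedSequence(seed)))


def build_mtl_network(config: ModelConfig, seed: int = 0, tied_init: bool = False) -> MTLNetwork:
    return MTLNetwork(config, seed=seed, tied_init=tied_init)


def build_single_task_baseline(config: ModelConfig, seed: int = 0) -> SingleTaskNetwork:
    return SingleTaskNetwork(config, seed=seed)
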