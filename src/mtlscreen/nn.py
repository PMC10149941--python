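"""Minimal NumPy neural-network core for the convolutional text classifiers.

Self-contained forward/backward primitives (trainable embedding, 1-D
convolution over token windows, global max pooling, inverted dropout, dense
layers, softmax, Adam) sufficient for the dual-branch multi-channel CNN.
Everything is float32 and seeded; with fixed seeds the whole training loop is
bit-stable on one platform.

Gradient conventions: each layer accumulates into ``Param.grad`` (callers zero
grads between steps).  L1/L2 weight penalties apply to convolution and dense
kernels only — not to embeddings or biases — matching how the downstream
models penalize "convolution and fully connected layers".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    regularized: bool = False

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def act_forward(x: np.ndarray, kind: str, alpha: float) -> np.ndarray:
    if kind == "relu":
        return np.maximum(x, 0.0)
    if kind == "leaky_relu":
        return np.where(x > 0.0, x, alpha * x)
    raise ValueError(f"unknown activation {kind!r}")


def act_backward(dy: np.ndarray, pre: np.ndarray, kind: str, alpha: float) -> np.ndarray:
    if kind == "relu":
        return dy * (pre > 0.0)
    if kind == "leaky_relu":
        return dy * np.where(pre > 0.0, 1.0, alpha)
    raise ValueError(f"unknown activation {kind!r}")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DenseLayer:
    """Fully connected layer ``y = act(x W + b)`` (``activation=None`` for logits)."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        activation: str | None = "relu",
        leaky_alpha: float = 0.2,
        regularized: bool = True,
    ):
        self.W = Param(glorot_uniform(rng, n_in, n_out, (n_in, n_out)), regularized=regularized)
        self.b = Param(np.zeros(n_out), regularized=False)
        self.activation = activation
        self.leaky_alpha = leaky_alpha
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        pre = x @ self.W.value + self.b.value
        out = pre if self.activation is None else act_forward(pre, self.activation, self.leaky_alpha)
        self._cache = (x, pre)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, pre = self._cache
        if self.activation is not None:
            dy = act_backward(dy, pre, self.activation, self.leaky_alpha)
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ConvStack:
    """Trainable embedding feeding parallel 1-D conv channels with global max
    pooling and dropout.

    For each channel (one per kernel size) the forward pass unfolds the
    embedded sequence into token windows, applies the convolution as a matrix
    product, activates, takes the per-filter maximum over time and applies
    inverted dropout.  Returns one (batch, n_filters) array per channel.
    """

    def __init__(
        self,
        vocab_size: int,
        embed_dim: int,
        kernel_sizes: Sequence[int],
        n_filters: int,
        dropout_p: float,
        activation: str,
        leaky_alpha: float,
        rng: np.random.Generator,
        embed_init_scale: float = 0.05,
    ):
        self.embed_dim = embed_dim
        self.kernel_sizes = list(kernel_sizes)
        self.n_filters = n_filters
        self.dropout_p = dropout_p
        self.activation = activation
        self.leaky_alpha = leaky_alpha
        self.E = Param(
            rng.uniform(-embed_init_scale, embed_init_scale, size=(vocab_size, embed_dim)),
            regularized=False,
        )
        self.convs: list[tuple[Param, Param]] = []
        for k in self.kernel_sizes:
            W = Param(
                glorot_uniform(rng, k * embed_dim, n_filters, (k * embed_dim, n_filters)),
                regularized=True,
            )
            b = Param(np.zeros(n_filters), regularized=False)
            self.convs.append((W, b))
        self._cache: dict | None = None

    @property
    def params(self) -> list[Param]:
        out = [self.E]
        for W, b in self.convs:
            out.extend([W, b])
        return out

    def forward(
        self, X: np.ndarray, train: bool, drop_rng: np.random.Generator | None
    ) -> list[np.ndarray]:
        B, L = X.shape
        if L < max(self.kernel_sizes):
            raise ValueError(
                f"sequence length {L} shorter than largest kernel {max(self.kernel_sizes)}"
            )
        Xe = self.E.value[X]  # (B, L, d)
        cache: dict = {"X": X, "shape": (B, L), "channels": []}
        pooled_out: list[np.ndarray] = []
        for (W, b), k in zip(self.convs, self.kernel_sizes):
            T = L - k + 1
            # windows: (B, T, k*d)
            U = np.lib.stride_tricks.sliding_window_view(Xe, k, axis=1)
            U = np.ascontiguousarray(U.transpose(0, 1, 3, 2)).reshape(B, T, k * self.embed_dim)
            pre = U.reshape(B * T, -1) @ W.value + b.value
            A = act_forward(pre, self.activation, self.leaky_alpha).reshape(B, T, self.n_filters)
            argmax = A.argmax(axis=1)  # (B, F)
            P = np.take_along_axis(A, argmax[:, None, :], axis=1)[:, 0, :]
            if train and self.dropout_p > 0.0:
                keep = 1.0 - self.dropout_p
                mask = (drop_rng.random(P.shape) < keep).astype(np.float32) / keep
            else:
                mask = None
            D = P * mask if mask is not None else P
            cache["channels"].append(
                {"U": U, "pre": pre, "argmax": argmax, "mask": mask, "T": T, "k": k}
            )
            pooled_out.append(D)
        self._cache = cache
        return pooled_out

    def backward(self, dpooled: Sequence[np.ndarray]) -> None:
        cache = self._cache
        X = cache["X"]
        B, L = cache["shape"]
        dXe = np.zeros((B, L, self.embed_dim), dtype=np.float32)
        for (W, b), ch, dD in zip(self.convs, cache["channels"], dpooled):
            T, k = ch["T"], ch["k"]
            dP = dD * ch["mask"] if ch["mask"] is not None else dD
            dA = np.zeros((B, T, self.n_filters), dtype=np.float32)
            np.put_along_axis(dA, ch["argmax"][:, None, :], dP[:, None, :], axis=1)
            dpre = act_backward(
                dA.reshape(B * T, self.n_filters), ch["pre"], self.activation, self.leaky_alpha
            )
            Uflat = ch["U"].reshape(B * T, -1)
            W.grad += Uflat.T @ dpre
            b.grad += dpre.sum(axis=0)
            dU = (dpre @ W.value.T).reshape(B, T, k, self.embed_dim)
            for j in range(k):
                dXe[:, j : j + T, :] += dU[:, :, j, :]
        np.add.at(self.E.grad, X.reshape(-1), dXe.reshape(-1, self.embed_dim))


class Adam:
    """Adam with a mutable learning rate (for plateau schedules)."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def apply_weight_penalty(params: Sequence[Param], l1: float, l2: float) -> float:
    """Add L1/L2 penalty gradients to regularized params; returns the penalty."""
    penalty = 0.0
    for p in params:
        if not p.regularized:
            continue
        w = p.value
        if l2:
            penalty += l2 * float(np.sum(np.square(w)))
            p.grad += (2.0 * l2) * w
        if l1:
            penalty += l1 * float(np.sum(np.abs(w)))
            p.grad += l1 * np.sign(w)
    return penalty


def get_weights(params: Sequence[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_weights(params: Sequence[Param], weights: Sequence[np.ndarray]) -> None:
    if len(params) != len(weights):
        raise ValueError("weight list length mismatch")
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError(f"shape mismatch: {p.value.shape} vs {w.shape}")
        p.value[...] = w
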