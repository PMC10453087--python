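"""Minimal NumPy neural-network engine for 1D convolutional classifiers.

Implements exactly the layer inventory the lightweight architectures need:
1D convolution (dense, grouped, depthwise), batch normalisation, ReLU, max
pooling, channel shuffle, dropout, dense layers, softmax cross-entropy and
Adam. Tensors are laid out (batch, channels, length); dense layers take
(batch, features).

Every layer caches what its backward pass needs during forward; a training
step is forward(training=True) -> loss backward -> layer.backward chain ->
optimizer.step(). Gradient correctness is guarded by finite-difference
tests rather than an autograd framework.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1D",
    "BatchNorm1D",
    "ReLU",
    "MaxPool1D",
    "ChannelShuffle",
    "Flatten",
    "Dropout",
    "Dense",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
    "Adam",
]


class Param:
    """A trainable array with its gradient accumulator.

    ``kind`` distinguishes convolution/dense weights from biases and batch-norm
    affine terms so weight-only counts (the classic "parameter saving"
    arithmetic, which excludes biases) can be audited separately.
    """

    def __init__(self, value: np.ndarray, kind: str = "weight") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.kind = kind


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        """Shape arithmetic: (channels, length) in -> (channels, length) out."""
        return spec


def _init_weight(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1D(Layer):
    """1D convolution with 'same' padding, stride and channel groups.

    groups=1 is a dense convolution; groups=in_channels with
    out_channels=in_channels is a depthwise convolution. Weight shape is
    (out_channels, in_channels // groups, kernel).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) must be divisible by "
                f"groups ({groups})"
            )
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel
        self.W = Param(_init_weight(rng, (out_channels, in_channels // groups, kernel), fan_in))
        self.b = Param(np.zeros(out_channels), kind="bias") if bias else None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _pad(self, L: int) -> tuple[int, int, int]:
        L_out = -(-L // self.stride)
        total = max((L_out - 1) * self.stride + self.kernel - L, 0)
        return L_out, total // 2, total - total // 2

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        L_out, pl, pr = self._pad(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        win = win[:, :, :: self.stride][:, :, :L_out]  # (B, C, L_out, k)
        g, cpg, opg = self.groups, C // self.groups, self.out_channels // self.groups
        out = np.empty((B, self.out_channels, L_out))
        for gi in range(g):
            wg = win[:, gi * cpg : (gi + 1) * cpg]
            Wg = self.W.value[gi * opg : (gi + 1) * opg]
            out[:, gi * opg : (gi + 1) * opg] = np.einsum(
                "bclk,ock->bol", wg, Wg, optimize=True
            )
        if self.b is not None:
            out += self.b.value[None, :, None]
        self._cache = (win, x.shape, pl)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        win, x_shape, pl = self._cache
        B, C, L = x_shape
        L_out = grad.shape[2]
        g, cpg, opg = self.groups, C // self.groups, self.out_channels // self.groups
        _, _, pr = self._pad(L)
        dxp = np.zeros((B, C, L + pl + pr))
        for gi in range(g):
            gy = grad[:, gi * opg : (gi + 1) * opg]
            wg = win[:, gi * cpg : (gi + 1) * cpg]
            Wg = self.W.value[gi * opg : (gi + 1) * opg]
            self.W.grad[gi * opg : (gi + 1) * opg] += np.einsum(
                "bclk,bol->ock", wg, gy, optimize=True
            )
            dpatch = np.einsum("bol,ock->bclk", gy, Wg, optimize=True)
            for kk in range(self.kernel):
                sl = slice(kk, kk + (L_out - 1) * self.stride + 1, self.stride)
                dxp[:, gi * cpg : (gi + 1) * cpg, sl] += dpatch[..., kk]
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2))
        return dxp[:, :, pl : pl + L]

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        _, L = spec
        return self.out_channels, -(-L // self.stride)


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels), kind="bn")
        self.beta = Param(np.zeros(channels), kind="bn")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, training)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, training = self._cache
        B, C, L = grad.shape
        n = B * L
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = grad * self.gamma.value[None, :, None]
        if not training:
            # eval mode: fixed affine map, no batch-statistic coupling
            return dxhat / std[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (dxhat - s1 / n - xhat * s2 / n) / std[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder shorter than the pool
    is dropped."""

    def __init__(self, pool: int = 2) -> None:
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, L = x.shape
        L_out = L // self.pool
        xr = x[:, :, : L_out * self.pool].reshape(B, C, L_out, self.pool)
        self._argmax = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, L = self._in_shape
        L_out = grad.shape[2]
        dxr = np.zeros((B, C, L_out, self.pool))
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=3)
        dx = np.zeros((B, C, L))
        dx[:, :, : L_out * self.pool] = dxr.reshape(B, C, L_out * self.pool)
        return dx

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        C, L = spec
        return C, L // self.pool


class ChannelShuffle(Layer):
    """Interleave channels across ``groups``: output channel i takes input
    channel (i mod g)*(C/g) + (i div g) — the reshape-transpose-flatten
    permutation that lets stacked group convolutions mix information."""

    def __init__(self, channels: int, groups: int) -> None:
        if channels % groups:
            raise ValueError(f"channels ({channels}) not divisible by groups ({groups})")
        self.channels = channels
        self.groups = groups
        i = np.arange(channels)
        self.perm = (i % groups) * (channels // groups) + i // groups
        self.inv_perm = np.argsort(self.perm)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x[:, self.perm]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, self.inv_perm]


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        C, L = spec
        return C * L, 1


class Dropout(Layer):
    """Inverted dropout; active only in training mode. Draws its masks from a
    shared generator so whole-network training is seed-deterministic."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.W = Param(_init_weight(rng, (in_features, out_features), in_features))
        self.b = Param(np.zeros(out_features), kind="bias")

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        return self.out_features, 1


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def out_spec(self, spec: tuple[int, int]) -> tuple[int, int]:
        for layer in self.layers:
            spec = layer.out_spec(spec)
        return spec


# ---------------------------------------------------------------------------
# Loss and optimiser
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits.
    ``targets`` are integer class indices."""
    B = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(p[np.arange(B), targets] + 1e-12).mean())
    dlogits = p.copy()
    dlogits[np.arange(B), targets] -= 1.0
    return loss, dlogits / B


class Adam:
    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
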