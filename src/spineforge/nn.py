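"""Layers and optimizer for the registration network.

Everything is seeded through ``numpy.random.Generator`` so two models built
with the same config and seed have bitwise-identical initial parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor, concat, conv2d, conv3d, conv3d_anisotropic

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _adam_update_py(p, g, m, v, lr_t, b1, b2, eps):
    for i in range(p.size):
        m[i] = b1 * m[i] + (1.0 - b1) * g[i]
        v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        p[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps)


_adam_update = _njit(cache=True)(_adam_update_py) if _njit else None


class Module:
    """Minimal parameter container with recursive collection."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad:
                    if id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out), dtype=DTYPE)
        else:
            w = _he_init(rng, (n_in, n_out), n_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, pad: int = 0, zero_init: bool = False):
        fan_in = c_in * kernel * kernel
        shape = (c_out, c_in, kernel, kernel)
        w = np.zeros(shape, dtype=DTYPE) if zero_init else _he_init(rng, shape, fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int | tuple,
                 rng: np.random.Generator, stride: int = 1, pad: int | tuple = 0,
                 zero_init: bool = False):
        k = (kernel,) * 3 if isinstance(kernel, int) else tuple(kernel)
        fan_in = c_in * int(np.prod(k))
        shape = (c_out, c_in, *k)
        w = np.zeros(shape, dtype=DTYPE) if zero_init else _he_init(rng, shape, fan_in)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)
        self.stride = stride
        self.pad = pad

    def __call__(self, x: Tensor) -> Tensor:
        if isinstance(self.pad, tuple):
            return conv3d_anisotropic(x, self.weight, self.bias, self.pad)
        return conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class SEBlock(Module):
    """Squeeze-and-excitation channel gating: global-average squeeze, a
    two-layer bottleneck, sigmoid excitation, channelwise rescale."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.channels = channels

    def __call__(self, x: Tensor) -> Tensor:
        nb, c = x.shape[:2]
        if c != self.channels:
            raise ValueError(f"SE block built for {self.channels} channels, got {c}")
        spatial_axes = tuple(range(2, x.ndim))
        z = x.mean(axis=spatial_axes)  # (B, C)
        gate = self.fc2(self.fc1(z).leaky_relu()).sigmoid()
        gate = gate.reshape((nb, c) + (1,) * (x.ndim - 2))
        return x * gate


def se_fuse(image_features: Tensor, annotation_features: Tensor,
            se_block: SEBlock) -> Tensor:
    """Channel-stack the two (batched) feature maps and apply SE gating."""
    if image_features.shape != annotation_features.shape:
        raise ValueError("image/annotation feature shapes differ")
    return se_block(concat([image_features, annotation_features], axis=1))


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2 ** self.t) / (1 - self.b1 ** self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if _adam_update is not None:
                _adam_update(p.data.reshape(-1), g.reshape(-1),
                             m.reshape(-1), v.reshape(-1),
                             DTYPE(lr_t), DTYPE(self.b1), DTYPE(self.b2),
                             DTYPE(self.eps))
            else:
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p.data -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(DTYPE)
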