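"""Minimal NumPy neural-network layers with explicit forward/backward passes.

All volumetric tensors are laid out ``(N, C, D, H, W)``. Every layer caches
what its backward pass needs during ``forward``; ``backward`` consumes the
upstream gradient and returns the gradient with respect to the layer input,
accumulating parameter gradients into ``Param.grad``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    """A learnable array together with its accumulated gradient."""

    data: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    training: bool = True

    def params(self) -> list[Param]:
        found: list[Param] = []
        for value in vars(self).values():
            if isinstance(value, Param):
                found.append(value)
            elif isinstance(value, Module):
                found.extend(value.params())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.params())
        return found

    def submodules(self) -> list["Module"]:
        subs: list[Module] = []
        for value in vars(self).values():
            if isinstance(value, Module):
                subs.append(value)
            elif isinstance(value, (list, tuple)):
                subs.extend(v for v in value if isinstance(v, Module))
        return subs

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for sub in self.submodules():
            sub.set_training(flag)

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_out: int,
                   dtype: np.dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_out)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv3d(Module):
    """3D cross-correlation with zero padding, implemented via im2col + GEMM."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_out = out_ch * kernel ** 3
        self.weight = Param(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel, kernel),
                                           fan_out, dtype))
        self.bias = Param(np.zeros(out_ch, dtype=dtype)) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        # win: (N, C, Do, Ho, Wo, k, k, k)
        y = np.tensordot(win, self.weight.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        y = np.moveaxis(y, -1, 1)
        if self.bias is not None:
            y += self.bias.data[None, :, None, None, None]
        self._cache = (xp, win, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, win, x_shape = self._cache
        k, s, p = self.kernel, self.stride, self.padding
        n, _, do, ho, wo = grad.shape
        self.weight.grad += np.tensordot(grad, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        gxp = np.zeros_like(xp)
        for a, b, c in itertools.product(range(k), repeat=3):
            # (N, Do, Ho, Wo, C) contribution of kernel offset (a, b, c)
            t = np.tensordot(grad, self.weight.data[:, :, a, b, c], axes=([1], [0]))
            gxp[:, :, a:a + s * do:s, b:b + s * ho:s, c:c + s * wo:s] += np.moveaxis(t, -1, 1)
        if p:
            gxp = gxp[:, :, p:-p, p:-p, p:-p]
        return gxp


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W) with running stats."""

    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32, zero_init_scale: bool = False) -> None:
        init = 0.0 if zero_init_scale else 1.0
        self.gamma = Param(np.full(channels, init, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        self._cache = (xhat, invstd)
        return self.gamma.data[None, :, None, None, None] * xhat \
            + self.beta.data[None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.data[None, :, None, None, None]
        if not self.training:
            return g * invstd[None, :, None, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        sum_g = g.sum(axis=axes, keepdims=True)
        sum_gx = (g * xhat).sum(axis=axes, keepdims=True)
        return (invstd[None, :, None, None, None] / m) * (m * g - sum_g - xhat * sum_gx)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.weight = Param(kaiming_normal(rng, (in_features, out_features),
                                           out_features, dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data.T


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        self.layers = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
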