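"""Volumetric convolutional block attention (channel gate then spatial gate).

Channel attention pools each feature map globally (mean and max), pushes both
summaries through a shared two-layer bottleneck (the 1x1x1-convolution MLP),
sums them and gates each channel multiplicatively. Spatial attention pools
across channels (mean and max), convolves the two pooled maps into a single
map and gates each voxel. The gate nonlinearity is sigmoid by default; a
softmax-over-channels variant of the channel gate is available for fidelity
experiments.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv3d, Module, Param, kaiming_normal, sigmoid, softmax

_BYPASS = object()


class ChannelAttention3d(Module):
    def __init__(self, channels: int, reduction: int, *, gate: str = "sigmoid",
                 rng: np.random.Generator, dtype=np.float32) -> None:
        if gate not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown gate {gate!r}")
        hidden = max(channels // reduction, 1)
        self.gate = gate
        self.w1 = Param(kaiming_normal(rng, (channels, hidden), hidden, dtype))
        self.b1 = Param(np.zeros(hidden, dtype=dtype))
        self.w2 = Param(kaiming_normal(rng, (hidden, channels), channels, dtype))
        self.b2 = Param(np.zeros(channels, dtype=dtype))
        self._cache = None
        self.bypass = False  # forces the gate to 1 (identity) for testing
        self.last_gate: np.ndarray | None = None

    def _mlp(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h_pre = s @ self.w1.data + self.b1.data
        h = np.maximum(h_pre, 0.0)
        return s, h, h @ self.w2.data + self.b2.data

    def _mlp_backward(self, s: np.ndarray, h: np.ndarray, gout: np.ndarray) -> np.ndarray:
        self.w2.grad += h.T @ gout
        self.b2.grad += gout.sum(axis=0)
        gh = (gout @ self.w2.data.T) * (h > 0)
        self.w1.grad += s.T @ gh
        self.b1.grad += gh.sum(axis=0)
        return gh @ self.w1.data.T

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.bypass:
            self.last_gate = np.ones(x.shape[:2], dtype=x.dtype)
            self._cache = (_BYPASS,)
            return x
        n, c, d, h, w = x.shape
        flat = x.reshape(n, c, -1)
        s_avg = flat.mean(axis=2)
        argmax = flat.argmax(axis=2)
        s_max = np.take_along_axis(flat, argmax[:, :, None], axis=2)[:, :, 0]
        sa, ha, za = self._mlp(s_avg)
        sm, hm, zm = self._mlp(s_max)
        logits = za + zm
        if self.gate == "sigmoid":
            gate = sigmoid(logits)
        else:
            gate = softmax(logits, axis=1)
        self.last_gate = gate
        self._cache = (x, sa, ha, sm, hm, gate, argmax)
        return x * gate[:, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache[0] is _BYPASS:
            return grad
        x, sa, ha, sm, hm, gate, argmax = self._cache
        n, c, d, h, w = x.shape
        dgate = (grad * x).sum(axis=(2, 3, 4))
        gx = grad * gate[:, :, None, None, None]
        if self.gate == "sigmoid":
            dlogits = dgate * gate * (1.0 - gate)
        else:
            dlogits = gate * (dgate - (dgate * gate).sum(axis=1, keepdims=True))
        dsa = self._mlp_backward(sa, ha, dlogits)
        dsm = self._mlp_backward(sm, hm, dlogits)
        gx += dsa[:, :, None, None, None] / (d * h * w)
        gflat = np.zeros((n, c, d * h * w), dtype=grad.dtype)
        np.put_along_axis(gflat, argmax[:, :, None], dsm[:, :, None], axis=2)
        return gx + gflat.reshape(x.shape)


class SpatialAttention3d(Module):
    def __init__(self, kernel: int = 7, *, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = Conv3d(2, 1, kernel, stride=1, padding=kernel // 2,
                           rng=rng, dtype=dtype)
        self._cache = None
        self.bypass = False
        self.last_gate: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.bypass:
            self.last_gate = np.ones((x.shape[0], 1) + x.shape[2:], dtype=x.dtype)
            self._cache = (_BYPASS,)
            return x
        avg = x.mean(axis=1, keepdims=True)
        argmax = x.argmax(axis=1)
        mx = np.take_along_axis(x, argmax[:, None], axis=1)
        pooled = np.concatenate([avg, mx], axis=1)
        gate = sigmoid(self.conv(pooled))
        self.last_gate = gate
        self._cache = (x, gate, argmax)
        return x * gate

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cache[0] is _BYPASS:
            return grad
        x, gate, argmax = self._cache
        c = x.shape[1]
        dgate = (grad * x).sum(axis=1, keepdims=True)
        gx = grad * gate
        dpre = dgate * gate * (1.0 - gate)
        dpooled = self.conv.backward(dpre)
        gx += dpooled[:, 0:1] / c
        gmax = np.zeros_like(x)
        np.put_along_axis(gmax, argmax[:, None], dpooled[:, 1:2], axis=1)
        return gx + gmax


class CBAM3d(Module):
    """Channel attention followed by spatial attention; output shape = input shape."""

    def __init__(self, channels: int, *, reduction: int = 8, spatial_kernel: int = 7,
                 gate: str = "sigmoid", use_channel: bool = True, use_spatial: bool = True,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.channel = ChannelAttention3d(channels, reduction, gate=gate,
                                          rng=rng, dtype=dtype) if use_channel else None
        self.spatial = SpatialAttention3d(spatial_kernel, rng=rng,
                                          dtype=dtype) if use_spatial else None

    def set_bypass(self, flag: bool) -> None:
        if self.channel is not None:
            self.channel.bypass = flag
        if self.spatial is not None:
            self.spatial.bypass = flag

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.channel is not None:
            x = self.channel(x)
        if self.spatial is not None:
            x = self.spatial(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.spatial is not None:
            grad = self.spatial.backward(grad)
        if self.channel is not None:
            grad = self.channel.backward(grad)
        return grad
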