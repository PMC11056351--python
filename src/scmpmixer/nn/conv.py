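"""Convolution layers used by the mixer blocks (channels-last layout).

Only the three convolution shapes the architecture needs are implemented:
patchifying convolution (kernel = stride = patch size), depthwise k x k
with "same" zero padding, and pointwise 1x1 (see ``layers.Dense``).
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .layers import Module, Parameter


class PatchifyConv(Module):
    """Convolution with kernel = stride = p: one output cell per patch.

    Implemented as a space-to-depth reshape followed by a single matmul,
    which is mathematically identical to the strided convolution.
    """

    def __init__(self, in_ch: int, out_ch: int, patch: int, rng: np.random.Generator):
        super().__init__()
        self.patch = patch
        self.in_ch = in_ch
        self.weight = Parameter(F.trunc_normal(rng, (patch * patch * in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def _space_to_depth(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        p = self.patch
        x = x.reshape(b, h // p, p, w // p, p, c)
        x = x.transpose(0, 1, 3, 2, 4, 5)
        return x.reshape(b, h // p, w // p, p * p * c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        p = self.patch
        if h % p or w % p:
            raise ValueError(
                f"patch size {p} does not divide spatial size {h}x{w}")
        self._shape = (b, h, w, c)
        self._patches = self._space_to_depth(x)
        return self._patches @ self.weight.data + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        p = self.patch
        k = self.weight.data.shape[0]
        d2d = dout.reshape(-1, dout.shape[-1])
        self.weight.grad += self._patches.reshape(-1, k).T @ d2d
        self.bias.grad += d2d.sum(axis=0)
        dpatches = dout @ self.weight.data.T
        dpatches = dpatches.reshape(b, h // p, w // p, p, p, c)
        dpatches = dpatches.transpose(0, 1, 3, 2, 4, 5)
        return dpatches.reshape(b, h, w, c)


class DepthwiseConv(Module):
    """Per-channel k x k correlation with "same" zero padding.

    Realized as k*k shifted multiply-accumulates, which keeps both passes
    vectorized without an im2col buffer.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("depthwise kernel must be odd for same padding")
        self.kernel = kernel
        self.channels = channels
        self.weight = Parameter(F.trunc_normal(rng, (kernel, kernel, channels)))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[-1]}")
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        self._xp = xp
        b, h, w, c = x.shape
        out = np.empty_like(x)
        out[...] = self.bias.data
        for u in range(k):
            for v in range(k):
                out += xp[:, u:u + h, v:v + w, :] * self.weight.data[u, v]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        pad = k // 2
        b, h, w, c = dout.shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        for u in range(k):
            for v in range(k):
                self.weight.grad[u, v] += np.einsum(
                    "bhwc,bhwc->c", dout, xp[:, u:u + h, v:v + w, :])
                dxp[:, u:u + h, v:v + w, :] += dout * self.weight.data[u, v]
        self.bias.grad += dout.sum(axis=(0, 1, 2))
        return dxp[:, pad:pad + h, pad:pad + w, :]


def upsample_nearest(x: np.ndarray, factor: int) -> np.ndarray:
    """Parameter-free nearest-neighbour upsampling of a channels-last map."""
    if factor == 1:
        return x
    return np.repeat(np.repeat(x, factor, axis=1), factor, axis=2)


def upsample_nearest_backward(dout: np.ndarray, factor: int) -> np.ndarray:
    """Adjoint of nearest upsampling: sum gradients over each replicated block."""
    if factor == 1:
        return dout
    b, hh, ww, c = dout.shape
    h, w = hh // factor, ww // factor
    return dout.reshape(b, h, factor, w, factor, c).sum(axis=(2, 4))
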