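"""ConvMixer branch: patch embedding plus depthwise-separable mixer blocks.

The patch embedding is a convolution whose kernel and stride both equal the
patch size p, followed by GELU and batch normalization; a W x H image maps
to a W/p x H/p grid with ``filters`` channels. Each mixer block is

    z' = BN(GELU(DepthwiseConv_3x3(x))) + x     (residual around the
    z  = BN(GELU(PointwiseConv(z')))             depthwise stage only)

with "same" padding on the depthwise stage so the residual shapes match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.conv import DepthwiseConv, PatchifyConv
from .nn.layers import BatchNorm, Dense, GELU, Module


@dataclass
class ConvMixerConfig:
    """patch_size p, filter count h, mixer depth, depthwise kernel side."""

    patch_size: int = 2
    filters: int = 128
    depth: int = 4
    dw_kernel: int = 3

    def validate(self, height: int, width: int):
        if min(self.patch_size, self.filters, self.dw_kernel) < 1 or self.depth < 0:
            raise ValueError("all ConvMixer counts must be >= 1 (depth >= 0)")
        if height % self.patch_size or width % self.patch_size:
            raise ValueError(
                f"patch size {self.patch_size} does not divide input "
                f"{height}x{width}")


class PatchEmbed(Module):
    """Conv(kernel=stride=p, h filters) -> GELU -> BN."""

    def __init__(self, in_ch: int, cfg: ConvMixerConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = PatchifyConv(in_ch, cfg.filters, cfg.patch_size, rng)
        self.act = GELU()
        self.bn = BatchNorm(cfg.filters)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.bn.forward(self.act.forward(self.conv.forward(x)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.act.backward(self.bn.backward(dout)))


class MixerBlock(Module):
    """Depthwise stage with residual, then pointwise stage (shape-preserving)."""

    def __init__(self, cfg: ConvMixerConfig, rng: np.random.Generator):
        super().__init__()
        h = cfg.filters
        self.dw = DepthwiseConv(h, cfg.dw_kernel, rng)
        self.act1 = GELU()
        self.bn1 = BatchNorm(h)
        self.pw = Dense(h, h, rng)  # pointwise = 1x1 conv over channels
        self.act2 = GELU()
        self.bn2 = BatchNorm(h)

    def forward(self, x: np.ndarray) -> np.ndarray:
        z_prime = self.bn1.forward(self.act1.forward(self.dw.forward(x))) + x
        return self.bn2.forward(self.act2.forward(self.pw.forward(z_prime)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dz_prime = self.pw.backward(self.act2.backward(self.bn2.backward(dout)))
        ddw = self.dw.backward(self.act1.backward(self.bn1.backward(dz_prime)))
        return ddw + dz_prime


class ConvMixerBranch(Module):
    """Patch embedding followed by ``depth`` mixer blocks."""

    def __init__(self, in_ch: int, cfg: ConvMixerConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embed = PatchEmbed(in_ch, cfg, rng)
        self.blocks = [MixerBlock(cfg, rng) for _ in range(cfg.depth)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.cfg.validate(x.shape[1], x.shape[2])
        y = self.embed.forward(x)
        for block in self.blocks:
            y = block.forward(y)
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for block in reversed(self.blocks):
            dout = block.backward(dout)
        return self.embed.backward(dout)
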