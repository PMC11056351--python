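"""Windowed and shifted-window self-attention (the SwTrans cycle).

A token grid ``(batch, grid_h, grid_w, dim)`` is cut into non-overlapping
``window x window`` blocks; multi-head self-attention runs inside each
block (W-MSA). The shifted pass (SW-MSA) first rolls the grid by ``shift``
along both axes so that tokens near former window borders share a window;
an additive mask keeps tokens that originate from different pre-shift
regions from attending to each other. One full cycle is

    z_hat      = W-MSA(LN(z_in))   + z_in
    z          = MLP(LN(z_hat))    + z_hat
    z_hat_next = SW-MSA(LN(z))     + z
    z_out      = MLP(LN(z_hat_next)) + z_hat_next

which is shape-preserving on the token grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import functional as F
from .nn.layers import Dense, Dropout, GELU, LayerNorm, Module, Parameter, Sequential

MASK_NEG = -1e9  # additive bias that zeroes attention after softmax


@dataclass
class SwinBlockConfig:
    """Hyperparameters of one attention cycle.

    window: side length of an attention window, in tokens.
    shift: cyclic-shift offset of the SW-MSA pass; 0 <= shift < window.
    heads: number of attention heads (must divide the embedding dim).
    mlp_dim: hidden width of the two-layer MLP.
    dropout_rate: dropout probability inside the MLP.
    use_relative_bias: learn a relative-position bias per head.
    """

    window: int = 7
    shift: int = 3
    heads: int = 4
    mlp_dim: int = 256
    dropout_rate: float = 0.1
    use_relative_bias: bool = True

    def validate(self, grid_h: int, grid_w: int, dim: int):
        if grid_h % self.window or grid_w % self.window:
            raise ValueError(
                f"window {self.window} must divide the token grid "
                f"{grid_h}x{grid_w}")
        if not 0 <= self.shift < self.window:
            raise ValueError(f"shift {self.shift} not in [0, window)")
        if dim % self.heads:
            raise ValueError(f"heads {self.heads} must divide dim {dim}")


# ---------------------------------------------------------------------------
# window plumbing
# ---------------------------------------------------------------------------

def window_partition(grid: np.ndarray, window: int) -> np.ndarray:
    """Cut ``(B, H, W, D)`` into ``(B * H/w * W/w, w*w, D)`` blocks.

    Tokens inside a block keep row-major order; every input token lands in
    exactly one block.
    """
    b, h, w, d = grid.shape
    if h % window or w % window:
        raise ValueError(
            f"window {window} does not divide grid {h}x{w}")
    x = grid.reshape(b, h // window, window, w // window, window, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(-1, window * window, d)


def window_reverse(blocks: np.ndarray, grid_h: int, grid_w: int,
                   window: int) -> np.ndarray:
    """Exact inverse of :func:`window_partition`."""
    nb, t, d = blocks.shape
    if t != window * window:
        raise ValueError(f"blocks have {t} tokens, expected {window * window}")
    n_windows = (grid_h // window) * (grid_w // window)
    if n_windows == 0 or nb % n_windows:
        raise ValueError(
            f"{nb} blocks inconsistent with grid {grid_h}x{grid_w}, "
            f"window {window}")
    b = nb // n_windows
    x = blocks.reshape(b, grid_h // window, grid_w // window, window, window, d)
    x = x.transpose(0, 1, 3, 2, 4, 5)
    return x.reshape(b, grid_h, grid_w, d)


def cyclic_shift(grid: np.ndarray, shift: int, direction: str = "forward") -> np.ndarray:
    """Roll the token grid by ``shift`` along both spatial axes.

    ``forward`` is the pre-attention shift (towards the upper-left);
    ``reverse`` undoes it. forward∘reverse is the identity.
    """
    if direction == "forward":
        s = -shift
    elif direction == "reverse":
        s = shift
    else:
        raise ValueError(f"direction must be forward|reverse, got {direction!r}")
    if shift == 0:
        return grid
    return np.roll(grid, (s, s), axis=(1, 2))


def attention_mask(grid_h: int, grid_w: int, window: int, shift: int) -> np.ndarray:
    """Per-window pairwise additive mask for the shifted pass.

    Returns ``(n_windows, window², window²)``: 0 where two tokens come from
    the same pre-shift region, a large negative value otherwise. All zeros
    when ``shift`` is 0.
    """
    n_windows = (grid_h // window) * (grid_w // window)
    t = window * window
    if shift == 0:
        return np.zeros((n_windows, t, t), dtype=np.float32)
    labels = np.zeros((1, grid_h, grid_w, 1), dtype=np.float32)
    region = 0
    for hs in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
        for ws in (slice(0, -window), slice(-window, -shift), slice(-shift, None)):
            labels[0, hs, ws, 0] = region
            region += 1
    win_labels = window_partition(labels, window).reshape(-1, t)
    diff = win_labels[:, None, :] != win_labels[:, :, None]
    return np.where(diff, np.float32(MASK_NEG), np.float32(0.0))


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

class WindowAttention(Module):
    """Multi-head self-attention over window blocks ``(n_blocks, T, dim)``.

    Optionally adds a learned relative-position bias (one scalar per head
    per token-offset pair) to the attention logits before the softmax.
    """

    def __init__(self, dim: int, heads: int, window: int,
                 rng: np.random.Generator, use_relative_bias: bool = True):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.window = window
        self.scale = 1.0 / np.sqrt(self.head_dim)
        self.qkv = Dense(dim, 3 * dim, rng)
        self.proj = Dense(dim, dim, rng)
        self.use_relative_bias = use_relative_bias
        if use_relative_bias:
            span = 2 * window - 1
            self.rel_table = Parameter(F.trunc_normal(rng, (span * span, heads)))
            coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                          indexing="ij")).reshape(2, -1)
            rel = coords[:, :, None] - coords[:, None, :] + (window - 1)
            self.rel_index = rel[0] * span + rel[1]  # (T, T), constant

    def forward(self, blocks: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        if not np.all(np.isfinite(blocks)):
            raise ValueError("non-finite values in attention input")
        nb, t, d = blocks.shape
        h, dh = self.heads, self.head_dim
        qkv = self.qkv.forward(blocks)
        qkv = qkv.reshape(nb, t, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        logits = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        if self.use_relative_bias:
            bias = self.rel_table.data[self.rel_index]  # (T, T, heads)
            logits = logits + bias.transpose(2, 0, 1)[None]
        if mask is not None:
            nw = mask.shape[0]
            bsz = nb // nw
            logits = logits.reshape(bsz, nw, h, t, t) + mask[None, :, None]
            logits = logits.reshape(nb, h, t, t)
        attn = F.softmax(logits, axis=-1)
        ctx = attn @ v
        y = ctx.transpose(0, 2, 1, 3).reshape(nb, t, d)
        self._cache = (q, k, v, attn, nb, t)
        return self.proj.forward(y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn, nb, t = self._cache
        h, dh, d = self.heads, self.head_dim, self.dim
        dy = self.proj.backward(dout)
        dctx = dy.reshape(nb, t, h, dh).transpose(0, 2, 1, 3)
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        dlogits = attn * (dattn - np.sum(dattn * attn, axis=-1, keepdims=True))
        if self.use_relative_bias:
            s = dlogits.sum(axis=0).transpose(1, 2, 0).reshape(-1, h)
            np.add.at(self.rel_table.grad, self.rel_index.reshape(-1), s)
        dq = (dlogits @ k) * self.scale
        dk = (dlogits.transpose(0, 1, 3, 2) @ q) * self.scale
        dqkv = np.stack([dq, dk, dv])  # (3, nb, heads, T, dh)
        dqkv = dqkv.transpose(1, 3, 0, 2, 4).reshape(nb, t, 3 * d)
        return self.qkv.backward(dqkv)


def multi_head_self_attention(block_tokens: np.ndarray, layer: WindowAttention,
                              mask: np.ndarray | None = None) -> np.ndarray:
    """Functional wrapper: apply a :class:`WindowAttention` layer to blocks."""
    return layer.forward(block_tokens, mask)


# ---------------------------------------------------------------------------
# cycle assembly
# ---------------------------------------------------------------------------

class _AttnStage(Module):
    """LN -> (shift) -> partition -> attention -> reverse -> (unshift).

    The residual addition lives in :class:`SwinCycle`.
    """

    def __init__(self, dim: int, grid_h: int, grid_w: int,
                 cfg: SwinBlockConfig, shift: int, rng: np.random.Generator):
        super().__init__()
        self.grid_h, self.grid_w = grid_h, grid_w
        self.window = cfg.window
        self.shift = shift
        self.ln = LayerNorm(dim)
        self.attn = WindowAttention(dim, cfg.heads, cfg.window, rng,
                                    cfg.use_relative_bias)
        self.mask = (attention_mask(grid_h, grid_w, cfg.window, shift)
                     if shift > 0 else None)

    def forward(self, grid: np.ndarray) -> np.ndarray:
        y = self.ln.forward(grid)
        if self.shift:
            y = cyclic_shift(y, self.shift, "forward")
        blocks = window_partition(y, self.window)
        blocks = self.attn.forward(blocks, self.mask)
        y = window_reverse(blocks, self.grid_h, self.grid_w, self.window)
        if self.shift:
            y = cyclic_shift(y, self.shift, "reverse")
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.shift:
            dout = cyclic_shift(dout, self.shift, "forward")
        dblocks = window_partition(dout, self.window)
        dblocks = self.attn.backward(dblocks)
        dy = window_reverse(dblocks, self.grid_h, self.grid_w, self.window)
        if self.shift:
            dy = cyclic_shift(dy, self.shift, "reverse")
        return self.ln.backward(dy)


class _MlpStage(Module):
    """LN -> FC(mlp_dim) -> GELU -> dropout -> FC(dim) -> dropout."""

    def __init__(self, dim: int, cfg: SwinBlockConfig, rng: np.random.Generator):
        super().__init__()
        self.ln = LayerNorm(dim)
        self.net = Sequential(
            Dense(dim, cfg.mlp_dim, rng), GELU(), Dropout(cfg.dropout_rate),
            Dense(cfg.mlp_dim, dim, rng), Dropout(cfg.dropout_rate))

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(self.ln.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.ln.backward(self.net.backward(dout))


class SwinCycle(Module):
    """One full W-MSA / SW-MSA cycle on a token grid (shape-preserving)."""

    def __init__(self, dim: int, grid_h: int, grid_w: int,
                 cfg: SwinBlockConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate(grid_h, grid_w, dim)
        self.wmsa = _AttnStage(dim, grid_h, grid_w, cfg, shift=0, rng=rng)
        self.mlp1 = _MlpStage(dim, cfg, rng)
        self.swmsa = _AttnStage(dim, grid_h, grid_w, cfg, shift=cfg.shift, rng=rng)
        self.mlp2 = _MlpStage(dim, cfg, rng)

    def forward(self, grid: np.ndarray) -> np.ndarray:
        z_hat = grid + self.wmsa.forward(grid)
        z = z_hat + self.mlp1.forward(z_hat)
        z_hat2 = z + self.swmsa.forward(z)
        return z_hat2 + self.mlp2.forward(z_hat2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout + self.mlp2.backward(dout)
        d = d + self.swmsa.backward(d)
        d = d + self.mlp1.backward(d)
        return d + self.wmsa.backward(d)
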