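"""SC-MP-Mixer assembly: multipath ConvMixer front-end, multipath Swin
stage, softmax head, and the seven ablation variants.

Stage 1 (MPCM) runs three ConvMixer branches at patch sizes 2/4/8 in
parallel, upsamples the coarser maps (nearest neighbour, strides 2 and 4)
to the finest grid and sums them element-wise, giving a
(input/2, input/2, filters) map. Stage 2 (MPST) extracts patch tokens at
two effective patch sizes from that map (a 1x1 convolution to
k = token_dim / p_eff**2 channels, then non-overlapping p_eff patching and
flattening to token_dim-wide vectors), runs Swin attention cycles on each
token grid, and concatenates the two token matrices along the token axis
(784 + 196 = 980 tokens of width 256 at the default configuration).
Stage 3 averages over tokens (GAP), applies a fully connected layer with
one output per class, and a softmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .convmixer_core import ConvMixerBranch, ConvMixerConfig
from .nn import functional as F
from .nn.conv import upsample_nearest, upsample_nearest_backward
from .nn.layers import Dense, Module
from .swin_core import SwinBlockConfig, SwinCycle

VARIANTS = ("convmixer_only", "swtrans_only", "mpcm_only", "mpcm_swtrans",
            "mpst_only", "convmixer_mpst", "full")

#: ablation numbering used in the reported comparison tables
VARIANT_TABLE_NAMES = {
    "convmixer_only": "Model 1", "swtrans_only": "Model 2",
    "mpcm_only": "Model 3", "mpcm_swtrans": "Model 4",
    "mpst_only": "Model 5", "convmixer_mpst": "Model 6", "full": "Model 7",
}


class ConfigError(ValueError):
    """Raised when an architecture configuration is internally inconsistent."""


@dataclass
class ModelConfig:
    """All architecture hyperparameters.

    mpst_grids are the token-grid side lengths of the two Swin branches on
    the (input/2)-sized stage-1 output; the effective patch sizes follow as
    (input/2) // grid and are reused wherever the multipath Swin stage is
    applied to a different spatial side (keeping token width = token_dim).
    """

    num_classes: int = 4
    input_size: int = 224
    mpcm_patches: tuple = (2, 4, 8)
    filters: int = 128
    depth: int = 4
    dw_kernel: int = 3
    upsample_strides: tuple = (2, 4)
    mpst_grids: tuple = (28, 14)
    token_dim: int = 256
    cycles_per_branch: int = 2
    swin: SwinBlockConfig = field(default_factory=SwinBlockConfig)
    variant: str = "full"
    seed: int = 0

    @property
    def mpst_patch_sizes(self) -> tuple:
        half = self.input_size // 2
        return tuple(half // g for g in self.mpst_grids)

    def validate(self):
        if self.variant not in VARIANTS:
            raise ConfigError(
                f"unknown variant {self.variant!r}; valid: {', '.join(VARIANTS)}")
        if self.num_classes < 2:
            raise ConfigError(f"num_classes must be >= 2, got {self.num_classes}")
        if self.input_size % (2 * max(self.mpcm_patches)):
            raise ConfigError(
                f"input_size {self.input_size} not divisible by "
                f"2*max(mpcm_patches)={2 * max(self.mpcm_patches)}")
        p0 = self.mpcm_patches[0]
        expected = tuple(p // p0 for p in self.mpcm_patches[1:])
        if tuple(self.upsample_strides) != expected:
            raise ConfigError(
                f"upsample_strides {self.upsample_strides} inconsistent with "
                f"mpcm_patches {self.mpcm_patches} (expected {expected})")
        half = self.input_size // 2
        for g in self.mpst_grids:
            if half % g:
                raise ConfigError(
                    f"token grid {g} does not divide input/2 = {half}")
            if g % self.swin.window:
                raise ConfigError(
                    f"window {self.swin.window} does not divide grid {g}")
        for p_eff in self.mpst_patch_sizes:
            if self.token_dim % (p_eff * p_eff):
                raise ConfigError(
                    f"k = token_dim/p_eff^2 = {self.token_dim}/{p_eff ** 2} "
                    f"is not a positive integer")
        if self.token_dim % self.swin.heads:
            raise ConfigError(
                f"heads {self.swin.heads} must divide token_dim {self.token_dim}")


def paper_config(num_classes: int = 4, variant: str = "full",
                 seed: int = 0) -> ModelConfig:
    """Full-scale defaults (224 input, 128 filters, 256-wide tokens)."""
    return ModelConfig(num_classes=num_classes, variant=variant, seed=seed)


def desk_config(num_classes: int = 3, variant: str = "full",
                seed: int = 0) -> ModelConfig:
    """Reduced desk-scale preset: input 112, filters 32, depth 2, token
    grids 14/7, 64-wide tokens, window 7, no dropout. Small enough to train
    on a single CPU in minutes while exercising every architectural path.
    """
    return ModelConfig(
        num_classes=num_classes, input_size=112, filters=32, depth=2,
        mpst_grids=(14, 7), token_dim=64,
        swin=SwinBlockConfig(window=7, shift=3, heads=4, mlp_dim=64,
                             dropout_rate=0.0),
        variant=variant, seed=seed)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

class PatchExtract(Module):
    """1x1 conv to k = token_dim/p_eff**2 channels, then non-overlapping
    p_eff x p_eff patching; each patch flattens to a token_dim-wide token.

    Output is kept as a token grid ``(B, side/p_eff, side/p_eff, token_dim)``
    for the attention cycles; flattening to the (B, T, token_dim) token
    matrix is a reshape.
    """

    def __init__(self, in_ch: int, p_eff: int, token_dim: int,
                 rng: np.random.Generator):
        super().__init__()
        if token_dim % (p_eff * p_eff):
            raise ConfigError(
                f"k = {token_dim}/{p_eff ** 2} is not a positive integer")
        self.p_eff = p_eff
        self.k = token_dim // (p_eff * p_eff)
        self.token_dim = token_dim
        self.conv = Dense(in_ch, self.k, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, s, s2, _ = x.shape
        p = self.p_eff
        if s % p or s2 % p:
            raise ConfigError(f"p_eff {p} does not divide map side {s}x{s2}")
        y = self.conv.forward(x)
        self._side = s
        y = y.reshape(b, s // p, p, s // p, p, self.k)
        y = y.transpose(0, 1, 3, 2, 4, 5)
        return y.reshape(b, s // p, s // p, self.token_dim)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b = dout.shape[0]
        s, p, k = self._side, self.p_eff, self.k
        d = dout.reshape(b, s // p, s // p, p, p, k)
        d = d.transpose(0, 1, 3, 2, 4, 5).reshape(b, s, s, k)
        return self.conv.backward(d)


class MPCM(Module):
    """Three parallel ConvMixer branches fused by upsample + element-wise sum."""

    def __init__(self, in_ch: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.branches = [
            ConvMixerBranch(in_ch, ConvMixerConfig(p, cfg.filters, cfg.depth,
                                                   cfg.dw_kernel), rng)
            for p in cfg.mpcm_patches]
        p0 = cfg.mpcm_patches[0]
        self.factors = [p // p0 for p in cfg.mpcm_patches]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = None
        for branch, f in zip(self.branches, self.factors):
            y = upsample_nearest(branch.forward(x), f)
            out = y if out is None else out + y
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = None
        for branch, f in zip(self.branches, self.factors):
            d = branch.backward(upsample_nearest_backward(dout, f))
            dx = d if dx is None else dx + d
        return dx


class MPST(Module):
    """Parallel patch-extraction + Swin-cycle branches; token matrices are
    concatenated along the token axis."""

    def __init__(self, in_ch: int, side: int, p_effs, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.extractors = []
        self.cycles = []
        self.grids = []
        for p_eff in p_effs:
            if side % p_eff:
                raise ConfigError(
                    f"p_eff {p_eff} does not divide spatial side {side}")
            g = side // p_eff
            self.grids.append(g)
            self.extractors.append(
                PatchExtract(in_ch, p_eff, cfg.token_dim, rng))
            self.cycles.append([
                SwinCycle(cfg.token_dim, g, g, cfg.swin, rng)
                for _ in range(cfg.cycles_per_branch)])
        self.token_dim = cfg.token_dim
        self.token_counts = [g * g for g in self.grids]

    def forward(self, x: np.ndarray) -> np.ndarray:
        outs = []
        for extract, cyc in zip(self.extractors, self.cycles):
            grid = extract.forward(x)
            for cycle in cyc:
                grid = cycle.forward(grid)
            b, gh, gw, d = grid.shape
            outs.append(grid.reshape(b, gh * gw, d))
        return np.concatenate(outs, axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = None
        offset = 0
        for extract, cyc, g, t in zip(self.extractors, self.cycles,
                                      self.grids, self.token_counts):
            d = dout[:, offset:offset + t, :].reshape(-1, g, g, self.token_dim)
            offset += t
            for cycle in reversed(cyc):
                d = cycle.backward(d)
            d = extract.backward(d)
            dx = d if dx is None else dx + d
        return dx


class GAPHead(Module):
    """Global average pooling over tokens (or spatial cells) -> FC -> softmax."""

    def __init__(self, dim: int, num_classes: int, rng: np.random.Generator):
        super().__init__()
        if num_classes < 2:
            raise ConfigError(f"num_classes must be >= 2, got {num_classes}")
        self.fc = Dense(dim, num_classes, rng)

    def forward(self, features: np.ndarray) -> np.ndarray:
        self._axes = tuple(range(1, features.ndim - 1))
        self._shape = features.shape
        pooled = features.mean(axis=self._axes)
        self.logits_ = self.fc.forward(pooled)
        return F.softmax(self.logits_, axis=-1)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backward from d(loss)/d(logits); softmax+loss grads are fused
        upstream (see ``nn.functional.softmax_cross_entropy``)."""
        dpooled = self.fc.backward(dlogits)
        n = int(np.prod([self._shape[a] for a in self._axes]))
        shape = [self._shape[0]] + [1] * len(self._axes) + [self._shape[-1]]
        return np.broadcast_to(dpooled.reshape(shape) / n, self._shape).copy()


def cross_entropy(targets_onehot: np.ndarray, probs: np.ndarray) -> float:
    """Categorical cross-entropy, batch mean (see ``nn.functional``)."""
    return F.cross_entropy(targets_onehot, probs)


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------

class SCMPMixer(Module):
    """The assembled network for any of the seven ablation variants.

    ``forward`` returns class probabilities; ``forward_features`` exposes
    the representation entering global average pooling (the concatenated
    token matrix for Swin-bearing variants), which is where the structural
    980 x 256 shape of the default configuration can be read off.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        v = cfg.variant
        half = cfg.input_size // 2
        p_effs = cfg.mpst_patch_sizes
        cm_cfg = ConvMixerConfig(cfg.mpcm_patches[0], cfg.filters, cfg.depth,
                                 cfg.dw_kernel)

        self.lift = None
        self.convmixer = None
        self.mpcm = None
        self.mpst = None
        if v == "convmixer_only":
            self.convmixer = ConvMixerBranch(3, cm_cfg, rng)
            head_dim = cfg.filters
        elif v == "swtrans_only":
            # single branch on the raw image; largest patch -> coarsest grid
            self.mpst = MPST(3, cfg.input_size, [max(p_effs)], cfg, rng)
            head_dim = cfg.token_dim
        elif v == "mpcm_only":
            self.mpcm = MPCM(3, cfg, rng)
            head_dim = cfg.filters
        elif v == "mpcm_swtrans":
            self.mpcm = MPCM(3, cfg, rng)
            self.mpst = MPST(cfg.filters, half, [p_effs[0]], cfg, rng)
            head_dim = cfg.token_dim
        elif v == "mpst_only":
            self.lift = Dense(3, cfg.filters, rng)  # 1x1 conv channel lift
            self.mpst = MPST(cfg.filters, cfg.input_size, p_effs, cfg, rng)
            head_dim = cfg.token_dim
        elif v == "convmixer_mpst":
            self.convmixer = ConvMixerBranch(3, cm_cfg, rng)
            self.mpst = MPST(cfg.filters, half, p_effs, cfg, rng)
            head_dim = cfg.token_dim
        else:  # full
            self.mpcm = MPCM(3, cfg, rng)
            self.mpst = MPST(cfg.filters, half, p_effs, cfg, rng)
            head_dim = cfg.token_dim
        self.head = GAPHead(head_dim, cfg.num_classes, rng)
        for g in (self.mpst.grids if self.mpst is not None else []):
            if g % cfg.swin.window:
                raise ConfigError(
                    f"window {cfg.swin.window} does not divide token grid {g} "
                    f"of variant {v!r}")

    # -- passes ----------------------------------------------------------
    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Representation entering GAP: a token matrix (B, T, token_dim)
        for Swin-bearing variants, a feature map otherwise."""
        if self.lift is not None:
            x = self.lift.forward(x)
        if self.convmixer is not None:
            x = self.convmixer.forward(x)
        if self.mpcm is not None:
            x = self.mpcm.forward(x)
        if self.mpst is not None:
            x = self.mpst.forward(x)
            self.token_count_ = x.shape[1]
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.forward_features(x))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        if self.mpst is not None:
            d = self.mpst.backward(d)
        if self.mpcm is not None:
            d = self.mpcm.backward(d)
        if self.convmixer is not None:
            d = self.convmixer.backward(d)
        if self.lift is not None:
            d = self.lift.backward(d)
        return d


def build_model(cfg: ModelConfig) -> SCMPMixer:
    """Build the requested ablation variant; raises ConfigError listing the
    valid names for an unknown variant."""
    return SCMPMixer(cfg)


def architecture_summary(model: SCMPMixer) -> dict:
    """JSON-serializable summary: variant, parameter counts per component."""
    per_component = {}
    for name in ("lift", "convmixer", "mpcm", "mpst", "head"):
        component = getattr(model, name)
        if component is not None:
            per_component[name] = component.num_parameters()
    return {
        "variant": model.cfg.variant,
        "input_size": model.cfg.input_size,
        "num_classes": model.cfg.num_classes,
        "token_dim": model.cfg.token_dim,
        "mpst_grids": list(model.mpst.grids) if model.mpst is not None else [],
        "parameters": model.num_parameters(),
        "parameters_by_component": per_component,
        "parameter_shapes": {n: list(p.data.shape)
                             for n, p in model.named_parameters()},
    }


def variant_config(cfg: ModelConfig, variant: str) -> ModelConfig:
    """A copy of ``cfg`` with a different ablation variant."""
    return replace(cfg, variant=variant)
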