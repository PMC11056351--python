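"""Minimal layer framework: explicit forward/backward, named parameters.

Layers cache whatever their backward pass needs on ``self`` during
``forward``; ``backward(dout)`` returns the gradient w.r.t. the input and
accumulates parameter gradients in ``Parameter.grad``. A layer instance is
used at one site in a network, so a single cache slot per layer suffices.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Parameter:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class; children are discovered from instance attributes.

    Attribute insertion order (fixed by ``__init__``) makes parameter
    ordering deterministic, which the optimizer and checkpoints rely on.
    """

    _buffer_names: tuple = ()  # non-trainable state (e.g. BN running stats)

    def __init__(self):
        self.training = False

    # -- traversal -------------------------------------------------------
    @staticmethod
    def _named_children(container, prefix):
        """Yield (name, Module) pairs, descending through nested lists."""
        if isinstance(container, Module):
            yield prefix, container
        elif isinstance(container, (list, tuple)):
            for i, item in enumerate(container):
                yield from Module._named_children(item, f"{prefix}.{i}")

    def children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                yield from self._named_children(val, name)

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self.children():
            yield from child.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self.children():
            yield from child.modules()

    def named_buffers(self, prefix: str = ""):
        for name, child in self.children():
            yield from child.named_buffers(f"{prefix}{name}.")
        for bname in self._buffer_names:
            yield prefix + bname, (self, bname)

    # -- state -----------------------------------------------------------
    def set_training(self, flag: bool):
        for m in self.modules():
            m.training = flag
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, (owner, attr) in self.named_buffers():
            state["buffer:" + name] = np.asarray(getattr(owner, attr)).copy()
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, (owner, attr) in self.named_buffers():
            setattr(owner, attr, state["buffer:" + name].copy())
        return self

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Dense(Module):
    """Affine map over the last axis: y = x @ W + b.

    Doubles as a pointwise (1x1) convolution when applied to
    channels-last feature maps.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim), dtype=np.float32)
        else:
            w = F.trunc_normal(rng, (in_dim, out_dim))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim, dtype=np.float32))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2d = self._x.reshape(-1, self._x.shape[-1])
        d2d = dout.reshape(-1, dout.shape[-1])
        self.weight.grad += x2d.T @ d2d
        self.bias.grad += d2d.sum(axis=0)
        return dout @ self.weight.data.T


class GELU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return F.gelu(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * F.gelu_grad(self._x)


class LayerNorm(Module):
    """Normalization over the embedding (last) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        d = xhat.shape[-1]
        flat = (-1, d)
        self.gamma.grad += (dout * xhat).reshape(flat).sum(axis=0)
        self.beta.grad += dout.reshape(flat).sum(axis=0)
        dxhat = dout * self.gamma.data
        mean_dxhat = dxhat.mean(axis=-1, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv_std * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)


class BatchNorm(Module):
    """Per-channel batch normalization for channels-last maps.

    Training uses batch statistics over (batch, height, width) and updates
    exponential running statistics (momentum 0.9); inference uses the
    running statistics, making evaluation deterministic and batch-size
    invariant.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.astype(np.float32)
            self.running_var = m * self.running_var + (1 - m) * var.astype(np.float32)
            self._n = x.size // x.shape[-1]
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu) * self._inv_std
            return self.gamma.data * self._xhat + self.beta.data
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        self._xhat = (x - self.running_mean) * inv_std
        self._inv_std = inv_std
        return self.gamma.data * self._xhat + self.beta.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = tuple(range(dout.ndim - 1))
        xhat = self._xhat
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.data
        if not self.training:
            return dxhat * self._inv_std
        n = self._n
        sum_dxhat = dxhat.sum(axis=axes)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes)
        return self._inv_std * (dxhat - sum_dxhat / n - xhat * sum_dxhat_xhat / n)


class Dropout(Module):
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


def attach_rng(module: Module, rng: np.random.Generator):
    """Point every Dropout in `module` at one shared generator (seeded runs)."""
    for m in module.modules():
        if isinstance(m, Dropout):
            m.rng = rng
    return module


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
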