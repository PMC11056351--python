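"""Stateless numerical primitives shared by all layers.

Everything here operates on plain ``numpy`` arrays in float32 (float64 is
accepted and preserved, which the finite-difference tests rely on).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)

PROB_EPS = 1e-7  # lower clamp for probabilities inside log()


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact (erf-based) Gaussian error linear unit."""
    return 0.5 * x * (1.0 + erf(x * _INV_SQRT2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d gelu(x) / dx = Phi(x) + x * phi(x)."""
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
    return cdf + x * pdf


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction)."""
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy(targets_onehot: np.ndarray, probs: np.ndarray) -> float:
    """Categorical cross-entropy L = -sum_k Y_k log(P_k), batch mean.

    Probabilities are clamped to ``[PROB_EPS, 1]`` so a zero probability at
    the true class yields a large finite loss rather than ``inf``.
    """
    p = np.clip(probs, PROB_EPS, 1.0)
    per_sample = -np.sum(targets_onehot * np.log(p), axis=-1)
    return float(np.mean(per_sample))


def softmax_cross_entropy(logits: np.ndarray, targets_onehot: np.ndarray):
    """Fused softmax + categorical cross-entropy.

    Returns ``(loss, probs, dlogits)`` where ``dlogits = (P - Y) / batch`` is
    the exact gradient of the batch-mean loss with respect to the logits.
    """
    probs = softmax(logits, axis=-1)
    loss = cross_entropy(targets_onehot, probs)
    dlogits = (probs - targets_onehot) / logits.shape[0]
    return loss, probs, dlogits


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init: resample draws outside two standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2.0 * std
    while np.any(bad):
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2.0 * std
    return x.astype(np.float32)
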