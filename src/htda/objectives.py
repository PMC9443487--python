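"""Joint training objective: classification loss plus weakly-supervised attention loss.

The total objective is

    L = alpha * L_C + (1 - alpha) * L_M

where L_C is softmax cross-entropy on the decoded prediction Y, and L_M is
a three-term penalty on the generated attention maps M_n (values in (0,1),
P elements each, N maps per inference):

    L_M = 1/(N P) * sum_n [ gamma * ||M_n||_1
                            - beta * ||M_n - mean(M_n)||_2^2
                            + (1 - gamma - beta) * ||M_n (*) Kern||_1 ]

The L1 term drives maps sparse (the convex stand-in for L0); the negated
variance term pushes gate values toward 0/1 (diversity — otherwise
everything settles at 0.5); the high-pass term (2-D correlation with a
Laplacian stencil) penalizes non-smooth maps so the attended region stays
integral.  No mask annotations are needed — the classification term keeps
the map from collapsing to all-zeros.

The high-pass kernel defaults to the 4-neighbor Laplacian with replicate
boundary handling, so any constant map incurs exactly zero smoothness
penalty and the all-ones / all-zeros degenerate cases stay analytic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import AttentionMap


@dataclass
class LossWeights:
    alpha: float = 0.10  # classification-vs-attention mix
    beta: float = 0.40  # variance (diversity) weight
    gamma: float = 0.51  # L1 (sparsity) weight

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if self.beta + self.gamma > 1.0 + 1e-12:
            raise ValueError(
                f"gamma + beta must not exceed 1 (smoothness weight 1-gamma-beta), got {self.gamma + self.beta}"
            )


LAPLACIAN_4 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class HighPassKernel:
    """Small zero-sum stencil applied to maps with replicate boundary."""

    stencil: np.ndarray = field(default_factory=lambda: LAPLACIAN_4.copy())

    def __post_init__(self):
        self.stencil = np.asarray(self.stencil, dtype=np.float64)
        if self.stencil.ndim != 2 or self.stencil.shape[0] != self.stencil.shape[1]:
            raise ValueError("high-pass stencil must be square")
        if self.stencil.shape[0] != 3:
            raise ValueError("only 3x3 stencils are supported (replicate pad width 1)")
        if abs(self.stencil.sum()) > 1e-12:
            raise ValueError("high-pass stencil coefficients must sum to 0")


def classification_loss(y: Tensor, labels: np.ndarray) -> Tensor:
    """Batch-mean softmax cross-entropy, -log softmax(Y)[label]."""
    labels = np.asarray(labels)
    n, n_classes = y.shape
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if labels.shape != (n,) or labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must be {n} class indices in [0,{n_classes})")
    # numerically stable log-sum-exp: subtracting a constant per row is
    # gradient-neutral, so the row max enters as data only
    shift = y.data.max(axis=1, keepdims=True)
    z = y - shift
    lse = ad.log(ad.exp(z).sum(axis=1, keepdims=True))
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), labels] = 1.0
    picked = (z * onehot).sum(axis=1, keepdims=True)
    return (lse - picked).mean()


def num_maps(k: int, td: float, tf: float) -> int:
    """Number of attention windows in an inference: floor(K*Td/Tf)."""
    if k <= 0 or td <= 0 or tf <= 0:
        raise ValueError("K, Td and Tf must be positive")
    return int(np.floor(k * td / tf + 1e-12))


def high_pass_response(map_values: Tensor, kernel: HighPassKernel) -> Tensor:
    """2-D correlation with the stencil under replicate boundary, same size out."""
    x = map_values
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:  # (N, H, W)
        x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    w = Tensor(kernel.stencil.reshape(1, 1, 3, 3))
    return ad.conv2d(ad.pad_replicate1(x), w, None, stride=1, padding=0)


def attention_loss(
    maps: list[AttentionMap] | list[Tensor],
    weights: LossWeights,
    kernel: HighPassKernel | None = None,
) -> Tensor:
    """The three-term attention penalty averaged over maps, elements and batch."""
    if not maps:
        raise ValueError("attention_loss needs at least one map")
    kernel = kernel or HighPassKernel()
    tensors: list[Tensor] = []
    for m in maps:
        t = m.values if isinstance(m, AttentionMap) else ad.as_tensor(m)
        if t.ndim == 2:
            t = t.reshape(1, 1, *t.shape)
        elif t.ndim == 3:
            t = t.reshape(t.shape[0], 1, t.shape[1], t.shape[2])
        tensors.append(t)
    p = tensors[0].shape[-2] * tensors[0].shape[-1]
    if any(t.shape[-2] * t.shape[-1] != p for t in tensors):
        raise ValueError("all attention maps must share the same element count")
    g, b = weights.gamma, weights.beta
    smooth_w = 1.0 - g - b
    axes = (1, 2, 3)
    total: Tensor | None = None
    for t in tensors:
        l1 = ad.absolute(t).sum(axis=axes)  # (N,)
        mu = t.mean(axis=axes, keepdims=True)
        centered = t - mu
        var_term = (centered * centered).sum(axis=axes)
        hp = ad.absolute(high_pass_response(t, kernel)).sum(axis=axes)
        term = g * l1 - b * var_term + smooth_w * hp
        total = term if total is None else total + term
    per_sample = total * (1.0 / (len(tensors) * p))
    return per_sample.mean()


def total_loss(l_c: Tensor | float, l_m: Tensor | float, alpha: float) -> Tensor:
    """L = alpha * L_C + (1 - alpha) * L_M."""
    return ad.as_tensor(l_c) * alpha + ad.as_tensor(l_m) * (1.0 - alpha)
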