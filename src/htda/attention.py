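"""Top-down attention-map generation and multiplicative input gating.

An analog (ReLU) generator network maps time-integrated spiking features to
a single-channel map at input resolution.  The raw map is standardized over
all of its elements (layer normalization without learned affine terms) and
squashed through a temperature-scaled sigmoid,

    M_n = sigmoid(Te * layernorm(A(mean of F over window n))),

so every generated gate lies strictly in (0,1).  The initial map M_0 is the
all-ones matrix (no spatial preference).  The temperature Te is annealed
linearly from 1 to a maximum (default 6) during training — a small Te keeps
sigmoid gradients alive early on, a large Te hardens the gates toward 0/1 —
and is held at the maximum at inference.

The generator defaults to three transposed-convolution layers (kernel 4,
stride 2, ReLU in between) tapping the extractor's penultimate stage;
stride-1 refinement layers (kernel 3) are substituted when less upsampling
is needed, so three layers always reach the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

_LN_EPS = 1e-5


@dataclass
class AttentionMap:
    """A spatial gate in [0,1] at input resolution, produced by window n."""

    values: Tensor  # (N, 1, H, W)
    index: int  # which Tf window produced it; 0 is the all-ones prior

    @classmethod
    def ones(cls, batch: int, height: int, width: int) -> "AttentionMap":
        return cls(values=Tensor(np.ones((batch, 1, height, width))), index=0)


@dataclass
class TemperatureSchedule:
    """Linear anneal of the sigmoid temperature from 1 to `maximum`."""

    maximum: float = 6.0
    span: int = 48  # epochs over which to anneal (default 80% of 60)
    start: float = 1.0

    def __call__(self, epoch: int, training: bool = True) -> float:
        if not training or self.span <= 0:
            return self.maximum
        frac = min(max(epoch, 0) / self.span, 1.0)
        return self.start + frac * (self.maximum - self.start)


def schedule_temperature(epoch: int, schedule: TemperatureSchedule, training: bool = True) -> float:
    return schedule(epoch, training=training)


def integrate_features(feature_steps: list[Tensor], tf: float | None = None, td: float | None = None) -> Tensor:
    """Elementwise mean of per-step features over one Tf window.

    When Tf and Td are given, the window length must equal Tf/Td (an integer).
    """
    if not feature_steps:
        raise ValueError("integrate_features needs a non-empty window")
    if tf is not None and td is not None:
        n = tf / td
        if abs(n - round(n)) > 1e-9 or round(n) != len(feature_steps):
            raise ValueError(
                f"window of {len(feature_steps)} steps inconsistent with Tf/Td = {tf}/{td}"
            )
    acc = feature_steps[0]
    for f in feature_steps[1:]:
        acc = acc + f
    return acc * (1.0 / len(feature_steps))


def layernorm(x: Tensor) -> Tensor:
    """Standardize over all elements of each sample's map (no learned affine)."""
    axes = tuple(range(1, x.ndim))
    mu = x.mean(axis=axes, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=axes, keepdims=True)
    return centered / ad.sqrt(var + _LN_EPS)


def squash_map(pre_map: Tensor, te: float, index: int = 1) -> AttentionMap:
    """Temperature sigmoid of the layer-normalized raw map -> gates in (0,1)."""
    if pre_map.size < 2:
        raise ValueError("squash_map needs at least 2 elements to normalize")
    return AttentionMap(values=ad.sigmoid(layernorm(pre_map) * te), index=index)


def modulate_input(frame: Tensor, amap: AttentionMap) -> Tensor:
    """Elementwise product X × M, the map broadcast across channels."""
    fs, ms = frame.shape[-2:], amap.values.shape[-2:]
    if fs != ms:
        raise ValueError(f"frame spatial size {fs} != map spatial size {ms}")
    return frame * amap.values


def _stride_plan(tap_size: int, out_size: int, n_layers: int = 3) -> list[int]:
    """Strides for `n_layers` deconv layers taking tap_size -> out_size."""
    if out_size % tap_size != 0:
        raise ValueError(f"input size {out_size} not a multiple of tap size {tap_size}")
    factor = out_size // tap_size
    strides = []
    for _ in range(n_layers):
        if factor > 1:
            strides.append(2)
            factor //= 2
        else:
            strides.append(1)
    if factor != 1:
        raise ValueError(f"cannot reach upsampling factor {out_size // tap_size} with {n_layers} stride-2 layers")
    return strides


class AttentionGenerator:
    """3-layer deconvolutional analog network from tap features to a raw map.

    Channel widths taper c -> c/2 -> c/4 -> 1.  Stride-2 layers use kernel 4
    padding 1 (×2 upsampling); stride-1 layers use kernel 3 padding 1.
    """

    def __init__(self, tap_channels: int, tap_size: int, out_size: int, rng: np.random.Generator):
        c = tap_channels
        widths = [c, max(c // 2, 1), max(c // 4, 1), 1]
        self.strides = _stride_plan(tap_size, out_size)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        last = len(self.strides) - 1
        for i, s in enumerate(self.strides):
            cin, cout = widths[i], widths[i + 1]
            k = 4 if s == 2 else 3
            fan_in = cin * k * k
            bound = float(np.sqrt(6.0 / fan_in))
            w = rng.uniform(-bound, bound, size=(cin, cout, k, k))
            if i == last:
                # non-negative output init: the initial raw map is positively
                # correlated with feature activity, so the closed loop starts
                # in the highlight-active-regions basin rather than a random
                # orientation (the feedback self-amplifies whichever side the
                # first maps favor)
                w = np.abs(w)
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(cout), requires_grad=True))

    def trainable(self) -> dict[str, Tensor]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"gen{i}_w"] = w
            out[f"gen{i}_b"] = b
        return out

    def __call__(self, integrated: Tensor) -> Tensor:
        x = integrated
        last = len(self.weights) - 1
        for i, (w, b, s) in enumerate(zip(self.weights, self.biases, self.strides)):
            x = ad.conv_transpose2d(x, w, b, stride=s, padding=1)
            if i != last:
                x = ad.relu(x)
        return x  # (N, 1, H, W) raw pre-normalization map


def generator_forward(generator: AttentionGenerator, integrated: Tensor) -> Tensor:
    """Raw (pre-normalization) single-channel map at input resolution."""
    return generator(integrated)
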