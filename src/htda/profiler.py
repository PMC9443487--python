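"""Firing-rate statistics, sparse-computation MAC estimation, parameter counts.

Firing rate is the proportion of firing neurons — per layer per time step,
and averaged over all layers and steps (total spikes divided by total
neurons across layers times K).

The MAC estimate follows event-driven accounting: a neuron that does not
fire triggers no post-synaptic computation, so each active unit entering a
layer contributes its fan-out synapse count (kernel support truncated at
borders times downstream channels).  The dense convolution count is defined
border-aware — the sum over output positions of the actual kernel support —
so the activity-density-1 limit of the sparse estimate equals the dense
count exactly.  The real-valued parts (encoder convolution on the gated
input, the attention generator per generated map, the linear decoder) are
counted densely; an optional mode skips exactly-zero encoder inputs,
mirroring the most optimistic accounting.  Accumulate-only spike operations
are reported in MAC units to keep a single unit; per-layer ACs are
available from the same report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network import HTDANetwork, InferenceTrace


@dataclass
class FiringRateReport:
    layers: list[str]
    per_layer_step: np.ndarray  # (n_layers, K) firing proportions
    mean_rate: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": self.layers,
                "per_layer_step": self.per_layer_step.tolist(),
                "mean_rate": self.mean_rate,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FiringRateReport":
        d = json.loads(s)
        return cls(d["layers"], np.asarray(d["per_layer_step"]), d["mean_rate"])


@dataclass
class MACReport:
    spiking_macs: int
    dense_macs: int
    params: int
    by_layer: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.spiking_macs + self.dense_macs

    def to_json(self) -> str:
        return json.dumps(
            {
                "spiking_macs": self.spiking_macs,
                "dense_macs": self.dense_macs,
                "params": self.params,
                "by_layer": self.by_layer,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "MACReport":
        d = json.loads(s)
        return cls(d["spiking_macs"], d["dense_macs"], d["params"], d["by_layer"])


def firing_rates(trace: InferenceTrace) -> FiringRateReport:
    """Per-layer, per-step firing proportions and the overall mean rate."""
    if not trace.spikes:
        raise ValueError("trace carries no spike records (run infer with collect=True)")
    layers = list(trace.spikes.keys())
    k = len(next(iter(trace.spikes.values())))
    table = np.zeros((len(layers), k))
    total_spikes = 0.0
    total_units = 0.0
    for li, name in enumerate(layers):
        for si, arr in enumerate(trace.spikes[name]):
            table[li, si] = float(arr.mean())
        per_sample_units = int(np.prod(trace.spikes[name][0].shape[1:]))
        batch = trace.spikes[name][0].shape[0]
        total_units += per_sample_units * batch
        total_spikes += sum(float(arr.sum()) for arr in trace.spikes[name])
    mean_rate = total_spikes / (total_units * k)
    return FiringRateReport(layers=layers, per_layer_step=table, mean_rate=float(mean_rate))


def conv_fanout_map(h: int, w: int, kernel: int = 3, padding: int = 1) -> np.ndarray:
    """Output positions reached by each input location (per in/out channel pair).

    For same-size 3x3 convolution this is 9 in the interior, 6 on edges and
    4 at corners; its sum equals the border-aware dense count per channel
    pair.
    """
    reach = kernel // 2 if padding else kernel - 1
    rows = np.array([min(i + reach, h - 1) - max(i - reach, 0) + 1 for i in range(h)])
    cols = np.array([min(j + reach, w - 1) - max(j - reach, 0) + 1 for j in range(w)])
    return rows[:, None] * cols[None, :]


def dense_conv_macs(h: int, w: int, cin: int, cout: int, kernel: int = 3, padding: int = 1) -> int:
    """Border-aware dense convolution count (actual multiplications, no zero pads)."""
    return int(conv_fanout_map(h, w, kernel, padding).sum()) * cin * cout


def _deconv_pair_count(h_in: int, w_in: int, kernel: int, stride: int, padding: int) -> int:
    """Connected (input, output) position pairs of a transposed convolution."""
    h_out = (h_in - 1) * stride - 2 * padding + kernel
    w_out = (w_in - 1) * stride - 2 * padding + kernel
    count = 0
    rows = np.zeros(h_in, dtype=int)
    for i in range(h_in):
        lo = i * stride - padding
        rows[i] = max(0, min(lo + kernel, h_out) - max(lo, 0))
    cols = np.zeros(w_in, dtype=int)
    for j in range(w_in):
        lo = j * stride - padding
        cols[j] = max(0, min(lo + kernel, w_out) - max(lo, 0))
    count = int(rows.sum() * cols.sum())
    return count


def generator_dense_macs(model: HTDANetwork) -> int:
    """Dense MACs of one attention-generator pass."""
    if model.generator is None:
        return 0
    gen = model.generator
    c = model.config
    tap_pools = sum(1 for p in model.POOL_AFTER if p < c.tap_stage)
    h = c.height // 2**tap_pools
    w = c.width // 2**tap_pools
    total = 0
    for wt, s in zip(gen.weights, gen.strides):
        cin, cout, kh, _ = wt.shape
        pairs = _deconv_pair_count(h, w, kh, s, 1)
        total += pairs * cin * cout
        h = (h - 1) * s - 2 + kh
        w = (w - 1) * s - 2 + kh
    return total


def estimate_macs(trace: InferenceTrace, model: HTDANetwork, skip_zero_encoder_input: bool = False) -> MACReport:
    """Event-driven MAC estimate for one traced inference (per batch as traced).

    Spiking path: each spike (after any pooling, counting nonzero pooled
    units) contributes its truncated fan-out into the next layer.  Dense
    path: encoder convolution, one generator pass per generated map, and
    the decoder.
    """
    if not trace.spikes:
        raise ValueError("trace carries no spike records (run infer with collect=True)")
    c = model.config
    k = c.k_steps
    batch = trace.spikes["conv1"][0].shape[0]
    by_layer: dict[str, int] = {}

    # dense encoder: real-valued gated input into conv1
    h, w = c.height, c.width
    if skip_zero_encoder_input and trace.gated_inputs:
        fan = conv_fanout_map(h, w)
        enc = 0.0
        for arr in trace.gated_inputs:  # (N, C, H, W)
            active = (arr != 0.0).sum(axis=1)  # (N, H, W) count of nonzero channels
            enc += float((active * fan[None]).sum()) * model.stage_widths[0]
        by_layer["conv1_dense"] = int(round(enc))
    else:
        by_layer["conv1_dense"] = dense_conv_macs(h, w, c.in_channels, model.stage_widths[0]) * k * batch

    # spiking path: conv_i spikes drive conv_{i+1}; conv6 (pooled) drives fc1; fc1 drives fc2
    spiking = 0
    sizes = []  # spatial size of each conv stage's output
    hh, ww = c.height, c.width
    for i in range(1, 7):
        sizes.append((hh, ww))
        if i in model.POOL_AFTER:
            hh //= 2
            ww //= 2
    for i in range(1, 6):  # conv_i -> conv_{i+1}
        pooled = i in model.POOL_AFTER
        cout_next = model.stage_widths[i]
        h_in, w_in = sizes[i]  # input size of conv_{i+1}
        fan = conv_fanout_map(h_in, w_in)
        layer_macs = 0.0
        for arr in trace.spikes[f"conv{i}"]:
            a = arr.astype(np.float64)
            if pooled:
                n_, c_, hh_, ww_ = a.shape
                a = a.reshape(n_, c_, hh_ // 2, 2, ww_ // 2, 2).mean(axis=(3, 5))
            active = (a != 0.0).sum(axis=1)  # (N, h_in, w_in)
            layer_macs += float((active * fan[None]).sum()) * cout_next
        by_layer[f"conv{i+1}_spiking"] = int(round(layer_macs))
        spiking += int(round(layer_macs))
    # conv6 (pooled, flattened) -> fc1
    fc1_macs = 0.0
    for arr in trace.spikes["conv6"]:
        a = arr.astype(np.float64)
        n_, c_, hh_, ww_ = a.shape
        a = a.reshape(n_, c_, hh_ // 2, 2, ww_ // 2, 2).mean(axis=(3, 5))
        fc1_macs += float((a != 0.0).sum()) * c.hidden
    by_layer["fc1_spiking"] = int(round(fc1_macs))
    spiking += int(round(fc1_macs))
    fc2_macs = sum(float(arr.sum()) for arr in trace.spikes["fc1"]) * c.n_classes
    by_layer["fc2_spiking"] = int(round(fc2_macs))
    spiking += int(round(fc2_macs))

    # dense generator passes and decoder
    n_generated = len(trace.generated_maps())
    gen_macs = generator_dense_macs(model) * n_generated * batch
    by_layer["generator_dense"] = gen_macs
    dec_macs = k * c.n_classes * c.n_classes * batch
    by_layer["decoder_dense"] = dec_macs

    dense = by_layer["conv1_dense"] + gen_macs + dec_macs
    return MACReport(
        spiking_macs=spiking, dense_macs=dense, params=count_params(model), by_layer=by_layer
    )


def count_params(model: HTDANetwork) -> int:
    """Total learnable scalars (weights, biases, decoder, generator, lam/V_th)."""
    return int(sum(p.data.size for p in model.params().values()))
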