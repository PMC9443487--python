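"""The closed-loop hybrid top-down attention (HTDA) spiking network.

Architecture: a real-valued input frame is gated elementwise by the current
attention map, encoded into spikes by the first convolutional LIF layer,
passed through a VGG-style spiking feature extractor E and a spiking
classifier C.  The classifier's per-step binary outputs are concatenated
over the K inference steps and decoded by a learnable linear read-out

    Y = w_C^T [F_C(Td), F_C(2 Td), ..., F_C(K Td)] + b_C,

a generalization of averaging the per-step predictions.  In parallel, the
spiking features at a tap stage are averaged over each attention window of
length Tf and fed to the analog generator, which produces the map used for
subsequent steps — a closed feedback loop unrolled over time and trained
end-to-end (gradients flow through the map, with no detaching).

Map cadence (window length w = Tf/Td):
  static inputs  — steps 1..w use the all-ones M_0, every later step reuses
                   M_1 generated once from the first window's features;
  dynamic inputs — steps of window n+1 use M_n, regenerated every window.

Backbone default: six 3x3 convolution stages with channel widths
(x, x, 2x, 2x, 4x, 4x) and 2x2 average pooling after stages 2, 4 and 6;
classifier = flatten -> spiking hidden layer -> spiking class layer.  Only
the encoder consumes real values; deeper layers consume binary spikes
(average-pooled between blocks).  All membrane potentials start at zero
for every inference, so identical inputs yield bit-identical traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .attention import AttentionGenerator, AttentionMap, integrate_features, modulate_input, squash_map
from .lif import LIFCell, LIFLayerState, LIFParams


@dataclass
class NetworkConfig:
    height: int = 32
    width: int = 32
    in_channels: int = 3
    base_channels: int = 32  # x in "VGG-xc"
    n_classes: int = 10
    hidden: int = 256
    k_steps: int = 6  # K: 6 for static, 10 for neuromorphic data
    td: float = 1.0  # ms
    tf: float = 2.0  # ms; attention-window length (Tf = 2 Td)
    attention: bool = True
    mode: str = "static"  # or "dynamic"
    learnable: bool = True  # learnable decay/threshold
    lam_init: float = 0.5
    v_th_init: float = 0.5
    surrogate_window: float = 0.5
    tap_stage: int = 5  # extractor stage whose output feeds the generator
    te_max: float = 6.0

    def __post_init__(self):
        w = self.tf / self.td
        if abs(w - round(w)) > 1e-9 or round(w) < 1:
            raise ValueError(f"Tf must be a positive integer multiple of Td, got Tf={self.tf}, Td={self.td}")
        if self.k_steps < round(w):
            raise ValueError(f"K={self.k_steps} must cover at least one window of {round(w)} steps")
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"mode must be 'static' or 'dynamic', got {self.mode!r}")
        if self.base_channels <= 0:
            raise ValueError("base_channels must be positive")

    @property
    def window_len(self) -> int:
        return int(round(self.tf / self.td))


@dataclass
class InferenceTrace:
    """Everything one inference produced, for decoding, losses and profiling."""

    y: Tensor  # (N, n_classes) decoded prediction
    logits: list  # K per-step classifier spike vectors (Tensors)
    maps: dict  # window index -> AttentionMap (only generated ones + M_0)
    map_indices: list  # map index applied at each step, length K
    spikes: dict = field(default_factory=dict)  # layer name -> list of per-step uint8 arrays
    gated_inputs: list = field(default_factory=list)  # per-step encoder inputs after gating (arrays)

    @property
    def prediction(self) -> np.ndarray:
        return np.argmax(self.y.data, axis=1)

    def generated_maps(self) -> list[AttentionMap]:
        return [m for n, m in sorted(self.maps.items()) if n > 0]


def attention_cadence(k: int, mode: str, window_len: int) -> int:
    """Map index applied at step k (1-based).

    Completed windows before step k: (k-1)//w.  Static inputs freeze the
    map after the first generation; dynamic inputs refresh every window.
    """
    if k < 1:
        raise ValueError("step index is 1-based")
    n = (k - 1) // window_len
    return min(n, 1) if mode == "static" else n


def decode_prediction(logits: list[Tensor], w_c: Tensor, b_c: Tensor) -> Tensor:
    """Learnable linear decoder over the concatenated per-step outputs."""
    cat = ad.concat(logits, axis=1)  # (N, K * n_classes)
    if cat.shape[1] != w_c.shape[0]:
        raise ValueError(f"decoder expects {w_c.shape[0]} features, got {cat.shape[1]}")
    return cat @ w_c + b_c


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / fan_in))
    return rng.uniform(-bound, bound, size=shape)


class _ConvLIF:
    def __init__(self, cin: int, cout: int, lif: LIFParams, rng: np.random.Generator):
        self.w = Tensor(_kaiming_uniform(rng, (cout, cin, 3, 3), cin * 9), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.cell = LIFCell(lif)

    def drive(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, stride=1, padding=1)


class _DenseLIF:
    def __init__(self, fin: int, fout: int, lif: LIFParams, rng: np.random.Generator):
        self.w = Tensor(_kaiming_uniform(rng, (fin, fout), fin), requires_grad=True)
        self.b = Tensor(np.zeros(fout), requires_grad=True)
        self.cell = LIFCell(lif)

    def drive(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class HTDANetwork:
    """Spike encoder + VGG-style extractor + spiking classifier + analog attention."""

    POOL_AFTER = (2, 4, 6)  # 1-based conv stages followed by 2x2 average pooling

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | int | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = c = config
        x = c.base_channels
        self.stage_widths = [x, x, 2 * x, 2 * x, 4 * x, 4 * x]
        lif = LIFParams(
            lam=c.lam_init, v_th=c.v_th_init, td=c.td,
            window=c.surrogate_window, learnable=c.learnable,
        )
        self.conv_layers: list[_ConvLIF] = []
        cin = c.in_channels
        for cout in self.stage_widths:
            self.conv_layers.append(_ConvLIF(cin, cout, lif, rng))
            cin = cout
        n_pools = len(self.POOL_AFTER)
        if c.height % (2**n_pools) or c.width % (2**n_pools):
            raise ValueError(f"input size {c.height}x{c.width} must be divisible by {2**n_pools}")
        self.flat_dim = self.stage_widths[-1] * (c.height // 2**n_pools) * (c.width // 2**n_pools)
        self.fc_hidden = _DenseLIF(self.flat_dim, c.hidden, lif, rng)
        self.fc_out = _DenseLIF(c.hidden, c.n_classes, lif, rng)
        self.dec_w = Tensor(
            _kaiming_uniform(rng, (c.k_steps * c.n_classes, c.n_classes), c.k_steps * c.n_classes),
            requires_grad=True,
        )
        self.dec_b = Tensor(np.zeros(c.n_classes), requires_grad=True)

        self.generator: AttentionGenerator | None = None
        if c.attention:
            tap_pools = sum(1 for p in self.POOL_AFTER if p < c.tap_stage)
            tap_size = c.height // 2**tap_pools
            tap_channels = self.stage_widths[c.tap_stage - 1]
            self.generator = AttentionGenerator(tap_channels, tap_size, c.height, rng)

    # -- parameters -----------------------------------------------------------

    def params(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for i, layer in enumerate(self.conv_layers, start=1):
            out[f"conv{i}_w"] = layer.w
            out[f"conv{i}_b"] = layer.b
            for k, v in layer.cell.trainable().items():
                out[f"conv{i}_{k}"] = v
        for name, layer in (("fc1", self.fc_hidden), ("fc2", self.fc_out)):
            out[f"{name}_w"] = layer.w
            out[f"{name}_b"] = layer.b
            for k, v in layer.cell.trainable().items():
                out[f"{name}_{k}"] = v
        out["dec_w"] = self.dec_w
        out["dec_b"] = self.dec_b
        if self.generator is not None:
            out.update(self.generator.trainable())
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters (trainable or frozen) for checkpointing."""
        out = {}
        for i, layer in enumerate(self.conv_layers, start=1):
            out[f"conv{i}_w"] = layer.w.data
            out[f"conv{i}_b"] = layer.b.data
            out[f"conv{i}_lam_raw"] = layer.cell.lam_raw.data
            out[f"conv{i}_v_th_raw"] = layer.cell.v_th_raw.data
        for name, layer in (("fc1", self.fc_hidden), ("fc2", self.fc_out)):
            out[f"{name}_w"] = layer.w.data
            out[f"{name}_b"] = layer.b.data
            out[f"{name}_lam_raw"] = layer.cell.lam_raw.data
            out[f"{name}_v_th_raw"] = layer.cell.v_th_raw.data
        out["dec_w"] = self.dec_w.data
        out["dec_b"] = self.dec_b.data
        if self.generator is not None:
            for k, v in self.generator.trainable().items():
                out[k] = v.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        holders: dict[str, Tensor] = {}
        for i, layer in enumerate(self.conv_layers, start=1):
            holders[f"conv{i}_w"] = layer.w
            holders[f"conv{i}_b"] = layer.b
            holders[f"conv{i}_lam_raw"] = layer.cell.lam_raw
            holders[f"conv{i}_v_th_raw"] = layer.cell.v_th_raw
        for name, layer in (("fc1", self.fc_hidden), ("fc2", self.fc_out)):
            holders[f"{name}_w"] = layer.w
            holders[f"{name}_b"] = layer.b
            holders[f"{name}_lam_raw"] = layer.cell.lam_raw
            holders[f"{name}_v_th_raw"] = layer.cell.v_th_raw
        holders["dec_w"] = self.dec_w
        holders["dec_b"] = self.dec_b
        if self.generator is not None:
            holders.update(self.generator.trainable())
        for name, holder in holders.items():
            if name not in arrays:
                raise KeyError(f"checkpoint missing array {name!r}")
            arr = np.asarray(arrays[name], dtype=np.float64)
            if arr.shape != holder.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {holder.data.shape}")
            holder.data = arr

    # -- forward --------------------------------------------------------------

    def encode(self, gated_frame: Tensor, state: LIFLayerState) -> tuple[LIFLayerState, Tensor]:
        """Encoding layer: convolution of the real-valued gated frame + one LIF step."""
        enc = self.conv_layers[0]
        return enc.cell.step(state, enc.drive(gated_frame))

    def _zero_states(self, n: int) -> dict:
        c = self.config
        states = {}
        h, w = c.height, c.width
        for i, cout in enumerate(self.stage_widths, start=1):
            states[f"conv{i}"] = LIFLayerState.zeros((n, cout, h, w))
            if i in self.POOL_AFTER:
                h //= 2
                w //= 2
        states["fc1"] = LIFLayerState.zeros((n, c.hidden))
        states["fc2"] = LIFLayerState.zeros((n, c.n_classes))
        return states

    def forward_step(self, frame: Tensor, amap: AttentionMap, states: dict) -> tuple[Tensor, Tensor, dict, dict]:
        """One inference step: gate, encode, extract, classify.

        Returns (tap features F, classifier spikes F_C, new states, per-layer spikes).
        """
        c = self.config
        x = modulate_input(frame, amap)
        spikes_by_layer: dict[str, Tensor] = {}
        tap_feat: Tensor | None = None
        new_states = dict(states)
        for i, layer in enumerate(self.conv_layers, start=1):
            name = f"conv{i}"
            new_states[name], s = layer.cell.step(states[name], layer.drive(x))
            spikes_by_layer[name] = s
            if i == c.tap_stage:
                tap_feat = s
            x = ad.avg_pool2d(s, 2) if i in self.POOL_AFTER else s
        x = x.reshape(x.shape[0], self.flat_dim)
        new_states["fc1"], s1 = self.fc_hidden.cell.step(states["fc1"], self.fc_hidden.drive(x))
        spikes_by_layer["fc1"] = s1
        new_states["fc2"], s2 = self.fc_out.cell.step(states["fc2"], self.fc_out.drive(s1))
        spikes_by_layer["fc2"] = s2
        return tap_feat, s2, new_states, spikes_by_layer

    def infer(
        self,
        frames: np.ndarray | Tensor,
        te: float | None = None,
        collect: bool = True,
    ) -> InferenceTrace:
        """Full K-step closed-loop inference.

        `frames` is (N, C, H, W) for static mode (replicated across steps) or
        (K, N, C, H, W) for dynamic mode.  `te` is the sigmoid temperature
        (defaults to the configured maximum, the inference-phase value).
        """
        c = self.config
        te = c.te_max if te is None else te
        if c.mode == "static":
            frame = ad.as_tensor(frames)
            if frame.ndim != 4:
                raise ValueError(f"static mode expects (N,C,H,W), got shape {frame.shape}")
            step_frames = [frame] * c.k_steps
        else:
            if isinstance(frames, Tensor):
                if frames.ndim != 5 or frames.shape[0] != c.k_steps:
                    raise ValueError(f"dynamic mode expects (K,N,C,H,W) with K={c.k_steps}")
                step_frames = _split_steps(frames, c.k_steps)
            else:
                arr = np.asarray(frames, dtype=np.float64)
                if arr.ndim != 5 or arr.shape[0] != c.k_steps:
                    raise ValueError(f"dynamic mode expects (K,N,C,H,W) with K={c.k_steps}, got {arr.shape}")
                step_frames = [Tensor(arr[k]) for k in range(c.k_steps)]
        n = step_frames[0].shape[0]
        w = c.window_len
        states = self._zero_states(n)
        maps: dict[int, AttentionMap] = {0: AttentionMap.ones(n, c.height, c.width)}
        window_feats: dict[int, list[Tensor]] = {}
        logits: list[Tensor] = []
        map_indices: list[int] = []
        spike_rec: dict[str, list[np.ndarray]] = {}
        gated_rec: list[np.ndarray] = []
        current_window: list[Tensor] = []
        for k in range(1, c.k_steps + 1):
            idx = attention_cadence(k, c.mode, w) if c.attention else 0
            if idx not in maps:
                pre = self.generator(integrate_features(window_feats[idx]))
                maps[idx] = squash_map(pre, te, index=idx)
            amap = maps[idx]
            map_indices.append(idx)
            frame_k = step_frames[k - 1]
            gated = modulate_input(frame_k, amap)
            if collect:
                gated_rec.append(gated.data)
            x = gated
            tap_feat = None
            for i, layer in enumerate(self.conv_layers, start=1):
                name = f"conv{i}"
                states[name], s = layer.cell.step(states[name], layer.drive(x))
                if collect:
                    spike_rec.setdefault(name, []).append(s.data.astype(np.uint8))
                if i == c.tap_stage:
                    tap_feat = s
                x = ad.avg_pool2d(s, 2) if i in self.POOL_AFTER else s
            x = x.reshape(n, self.flat_dim)
            states["fc1"], s1 = self.fc_hidden.cell.step(states["fc1"], self.fc_hidden.drive(x))
            states["fc2"], s2 = self.fc_out.cell.step(states["fc2"], self.fc_out.drive(s1))
            if collect:
                spike_rec.setdefault("fc1", []).append(s1.data.astype(np.uint8))
                spike_rec.setdefault("fc2", []).append(s2.data.astype(np.uint8))
            logits.append(s2)
            if c.attention:
                current_window.append(tap_feat)
                if k % w == 0:
                    window_feats[k // w] = current_window
                    current_window = []
        y = decode_prediction(logits, self.dec_w, self.dec_b)
        return InferenceTrace(
            y=y, logits=logits, maps=maps, map_indices=map_indices,
            spikes=spike_rec, gated_inputs=gated_rec,
        )


def _split_steps(frames: Tensor, k_steps: int) -> list[Tensor]:
    """Differentiable per-step slices of a (K, N, C, H, W) tensor."""
    outs = []
    for k in range(k_steps):
        data = frames.data[k]

        def backward(g, parent=frames, kk=k):
            full = np.zeros_like(parent.data)
            full[kk] = g
            parent._accum(full)

        outs.append(frames._make(data, (frames,), backward))
    return outs
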