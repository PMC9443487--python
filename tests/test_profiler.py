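"""Firing-rate statistics, event-driven MAC accounting, parameter counting."""

import numpy as np
import pytest

from htda.network import HTDANetwork, InferenceTrace, NetworkConfig
from htda.profiler import (
    FiringRateReport,
    MACReport,
    conv_fanout_map,
    count_params,
    dense_conv_macs,
    estimate_macs,
    firing_rates,
)


def _trace_with_spikes(spikes):
    from htda.autodiff import Tensor

    return InferenceTrace(y=Tensor(np.zeros((1, 2))), logits=[], maps={}, map_indices=[], spikes=spikes)


class TestFiringRates:
    def test_all_zero_and_all_one(self):
        zeros = {f"l{i}": [np.zeros((2, 3), dtype=np.uint8)] * 4 for i in range(3)}
        rep = firing_rates(_trace_with_spikes(zeros))
        assert np.all(rep.per_layer_step == 0.0) and rep.mean_rate == 0.0
        ones = {f"l{i}": [np.ones((2, 3), dtype=np.uint8)] * 4 for i in range(3)}
        rep = firing_rates(_trace_with_spikes(ones))
        assert np.all(rep.per_layer_step == 1.0) and rep.mean_rate == 1.0

    def test_hand_built_counts(self):
        # 3 layers x 2 steps with known spike counts, against direct counting
        rng = np.random.default_rng(0)
        spikes = {
            name: [rng.integers(0, 2, size=(2, 5)).astype(np.uint8) for _ in range(2)]
            for name in ("a", "b", "c")
        }
        rep = firing_rates(_trace_with_spikes(spikes))
        for li, name in enumerate(rep.layers):
            for si in range(2):
                assert rep.per_layer_step[li, si] == spikes[name][si].mean()
        total = sum(s.sum() for steps in spikes.values() for s in steps)
        units = 3 * 2 * 5  # layers x batch x neurons
        assert rep.mean_rate == pytest.approx(total / (units * 2))

    def test_missing_records_rejected(self):
        with pytest.raises(ValueError):
            firing_rates(_trace_with_spikes({}))

    def test_report_roundtrip(self):
        rep = FiringRateReport(["a"], np.array([[0.5, 0.25]]), 0.375)
        back = FiringRateReport.from_json(rep.to_json())
        assert back.layers == rep.layers
        np.testing.assert_array_equal(back.per_layer_step, rep.per_layer_step)
        assert back.mean_rate == rep.mean_rate


class TestFanout:
    def test_interior_edge_corner(self):
        fan = conv_fanout_map(5, 5)
        assert fan[2, 2] == 9 and fan[0, 2] == 6 and fan[0, 0] == 4

    def test_single_interior_spike_fanout(self):
        # one spike into a 3x3-kernel 4-channel layer drives 9*4 = 36 MACs
        fan = conv_fanout_map(8, 8)
        assert fan[4, 4] * 4 == 36

    def test_dense_count_is_fanout_sum(self):
        # the border-aware dense count and the fan-out accounting agree by
        # construction (both count connected in/out position pairs)
        h, w, cin, cout = 6, 7, 3, 5
        assert dense_conv_macs(h, w, cin, cout) == int(conv_fanout_map(h, w).sum()) * cin * cout


@pytest.fixture(scope="module")
def profiled_model():
    cfg = NetworkConfig(
        height=16, width=16, in_channels=1, base_channels=4, n_classes=2,
        hidden=16, k_steps=4,
    )
    model = HTDANetwork(cfg, rng=0)
    from htda.data import make_scene_dataset

    images, _, _ = make_scene_dataset(3, seed=2, label_mode="texture")
    trace = model.infer(images, collect=True)
    return model, trace


class TestEstimateMacs:
    def test_zero_spikes_leaves_dense_parts_only(self, profiled_model):
        model, trace = profiled_model
        silent = {name: [np.zeros_like(s) for s in steps] for name, steps in trace.spikes.items()}
        t2 = InferenceTrace(
            y=trace.y, logits=trace.logits, maps=trace.maps,
            map_indices=trace.map_indices, spikes=silent, gated_inputs=trace.gated_inputs,
        )
        rep = estimate_macs(t2, model)
        assert rep.spiking_macs == 0
        assert rep.total == rep.dense_macs > 0

    def test_full_density_equals_dense_convolution_count(self, profiled_model):
        model, trace = profiled_model
        k, batch = 4, trace.spikes["conv1"][0].shape[0]
        saturated = {name: [np.ones_like(s) for s in steps] for name, steps in trace.spikes.items()}
        t2 = InferenceTrace(
            y=trace.y, logits=trace.logits, maps=trace.maps,
            map_indices=trace.map_indices, spikes=saturated, gated_inputs=trace.gated_inputs,
        )
        rep = estimate_macs(t2, model)
        widths = model.stage_widths
        want = 0
        sizes = [(16, 16), (16, 16), (8, 8), (8, 8), (4, 4), (4, 4)]
        for i in range(1, 6):  # conv_{i+1} consumes conv_i activity
            h, w = sizes[i]
            want += dense_conv_macs(h, w, widths[i - 1], widths[i]) * k * batch
        want += widths[-1] * 2 * 2 * model.config.hidden * k * batch  # flatten -> fc1
        want += model.config.hidden * model.config.n_classes * k * batch
        assert rep.spiking_macs == want

    def test_monotone_in_spikes(self, profiled_model):
        model, trace = profiled_model
        base = estimate_macs(trace, model).spiking_macs
        bumped = {n: [s.copy() for s in steps] for n, steps in trace.spikes.items()}
        arr = bumped["conv3"][1]
        idx = np.unravel_index(np.argmin(arr), arr.shape)
        arr[idx] = 1  # add one spike
        t2 = InferenceTrace(
            y=trace.y, logits=trace.logits, maps=trace.maps,
            map_indices=trace.map_indices, spikes=bumped, gated_inputs=trace.gated_inputs,
        )
        assert estimate_macs(t2, model).spiking_macs >= base

    def test_report_roundtrip(self, profiled_model):
        model, trace = profiled_model
        rep = estimate_macs(trace, model)
        back = MACReport.from_json(rep.to_json())
        assert back.total == rep.total and back.by_layer == rep.by_layer


class TestCountParams:
    def test_known_architecture_count(self):
        cfg = NetworkConfig(
            height=16, width=16, in_channels=1, base_channels=2, n_classes=2,
            hidden=8, k_steps=4, attention=False, learnable=False,
        )
        model = HTDANetwork(cfg, rng=0)
        widths = [2, 2, 4, 4, 8, 8]
        want, cin = 0, 1
        for w in widths:
            want += w * cin * 9 + w
            cin = w
        want += 8 * 2 * 2 * 8 + 8  # flatten(8 ch * 2x2) -> hidden 8
        want += 8 * 2 + 2  # hidden -> classes
        want += 4 * 2 * 2 + 2  # decoder (K*classes -> classes) + bias
        assert count_params(model) == want

    def test_learnable_scalars_counted(self):
        base = dict(
            height=16, width=16, in_channels=1, base_channels=2, n_classes=2,
            hidden=8, k_steps=4, attention=False,
        )
        frozen = HTDANetwork(NetworkConfig(**base, learnable=False), rng=0)
        learn = HTDANetwork(NetworkConfig(**base, learnable=True), rng=0)
        # one decay + one threshold per spiking layer (6 conv + 2 dense)
        assert count_params(learn) - count_params(frozen) == 2 * 8

    def test_matches_enumeration_oracle(self):
        cfg = NetworkConfig(
            height=16, width=16, in_channels=1, base_channels=4, n_classes=3,
            hidden=16, k_steps=4,
        )
        model = HTDANetwork(cfg, rng=0)
        want = sum(int(np.prod(t.data.shape)) for t in model.params().values())
        assert count_params(model) == want
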