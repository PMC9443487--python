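"""Closed-loop network: cadence, decoding, encoder, trace contracts."""

import numpy as np
import pytest

from htda import autodiff as ad
from htda.autodiff import Tensor
from htda.lif import LIFLayerState
from htda.network import HTDANetwork, NetworkConfig, attention_cadence, decode_prediction

from conftest import loop_conv2d, scalar_lif_trace


class TestAttentionCadence:
    def test_static_k6(self):
        # first window runs on the all-ones prior; the single generated map
        # is shared by every later step
        got = [attention_cadence(k, "static", 2) for k in range(1, 7)]
        assert got == [0, 0, 1, 1, 1, 1]

    def test_dynamic_k10(self):
        got = [attention_cadence(k, "dynamic", 2) for k in range(1, 11)]
        assert got == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_single_window_always_prior(self):
        for mode in ("static", "dynamic"):
            assert [attention_cadence(k, mode, 4) for k in range(1, 5)] == [0, 0, 0, 0]

    def test_one_based_contract(self):
        with pytest.raises(ValueError):
            attention_cadence(0, "static", 2)


class TestDecodePrediction:
    def test_block_averaging_weights(self):
        # w_C assembled to average the two per-step outputs
        w = np.vstack([np.eye(2), np.eye(2)]) * 0.5
        logits = [Tensor(np.array([[1.0, 0.0]])), Tensor(np.array([[0.0, 1.0]]))]
        y = decode_prediction(logits, Tensor(w), Tensor(np.zeros(2)))
        np.testing.assert_allclose(y.data, [[0.5, 0.5]])

    def test_zero_weights_give_bias(self):
        logits = [Tensor(np.zeros((3, 2)))] * 2
        y = decode_prediction(logits, Tensor(np.zeros((4, 2))), Tensor(np.array([0.3, -0.1])))
        np.testing.assert_allclose(y.data, np.tile([0.3, -0.1], (3, 1)))

    def test_matches_matrix_product_oracle(self, rng):
        k, c = 3, 4
        logits = [rng.uniform(size=(2, c)) for _ in range(k)]
        w = rng.normal(size=(k * c, c))
        b = rng.normal(size=c)
        y = decode_prediction([Tensor(l) for l in logits], Tensor(w), Tensor(b)).data
        want = np.concatenate(logits, axis=1) @ w + b
        np.testing.assert_allclose(y, want, atol=1e-12)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_prediction([Tensor(np.zeros((1, 2)))], Tensor(np.zeros((4, 2))), Tensor(np.zeros(2)))


class TestEncoder:
    def test_zero_frame_no_spikes(self, tiny_net_config):
        model = HTDANetwork(tiny_net_config, rng=0)
        model.conv_layers[0].b.data[:] = 0.0
        state = LIFLayerState.zeros((1, tiny_net_config.base_channels, 16, 16))
        _, spikes = model.encode(Tensor(np.zeros((1, 1, 16, 16))), state)
        assert np.all(spikes.data == 0.0)

    def test_zero_gated_region_stays_silent(self, tiny_net_config):
        # a receptive field wholly inside a zero-gated region gets no drive
        model = HTDANetwork(tiny_net_config, rng=0)
        model.conv_layers[0].b.data[:] = 0.0
        frame = np.random.default_rng(0).uniform(size=(1, 1, 16, 16))
        frame[:, :, :8, :] = 0.0  # as if gated to zero
        state = LIFLayerState.zeros((1, tiny_net_config.base_channels, 16, 16))
        _, spikes = model.encode(Tensor(frame), state)
        assert np.all(spikes.data[:, :, :7, :] == 0.0)

    def test_matches_conv_plus_scalar_lif_oracle(self, rng):
        cfg = NetworkConfig(
            height=8, width=8, in_channels=1, base_channels=2, n_classes=2,
            hidden=8, k_steps=2, learnable=False,
        )
        model = HTDANetwork(cfg, rng=1)
        enc = model.conv_layers[0]
        frames = rng.uniform(size=(3, 1, 1, 8, 8))
        state = LIFLayerState.zeros((1, 2, 8, 8))
        got = []
        for f in frames:
            state, s = model.encode(Tensor(f), state)
            got.append(s.data)
        drives = np.stack([loop_conv2d(f, enc.w.data, enc.b.data, padding=1) for f in frames])
        lam = float(ad.sigmoid(enc.cell.lam_raw).data)
        v_th = float(enc.cell.v_th.data)
        flat = drives.reshape(3, -1)
        for j in range(flat.shape[1]):
            want = scalar_lif_trace(flat[:, j], lam, v_th)
            np.testing.assert_array_equal(np.stack(got).reshape(3, -1)[:, j], want)


class TestInfer:
    def test_attention_disabled_equals_all_ones_gating(self, tiny_net_config, tiny_scenes):
        import dataclasses

        images = tiny_scenes[0][:4]
        on = HTDANetwork(tiny_net_config, rng=3)
        off_cfg = dataclasses.replace(tiny_net_config, attention=False)
        off = HTDANetwork(off_cfg, rng=3)
        off.load_state_arrays({k: v for k, v in on.state_arrays().items() if not k.startswith("gen")})
        t_on = on.infer(images)
        t_off = off.infer(images)
        # the ablation departs from the full model only through generated
        # maps: during the first window both run under the all-ones M_0 and
        # must agree bit-for-bit
        np.testing.assert_array_equal(t_on.logits[0].data, t_off.logits[0].data)
        np.testing.assert_array_equal(t_on.logits[1].data, t_off.logits[1].data)
        assert t_off.map_indices == [0] * 4
        assert set(np.unique(t_off.maps[0].values.data)) == {1.0}

    def test_inference_deterministic(self, tiny_net_config, tiny_scenes):
        model = HTDANetwork(tiny_net_config, rng=5)
        images = tiny_scenes[0][:4]
        t1 = model.infer(images)
        t2 = model.infer(images)
        np.testing.assert_array_equal(t1.y.data, t2.y.data)
        for n in t1.maps:
            np.testing.assert_array_equal(t1.maps[n].values.data, t2.maps[n].values.data)

    def test_no_cross_sample_leakage(self, tiny_net_config, tiny_scenes):
        # states reset between inferences: per-sample outputs are independent
        # of batch composition and order
        model = HTDANetwork(tiny_net_config, rng=5)
        images = tiny_scenes[0][:6]
        full = model.infer(images).y.data
        perm = np.array([3, 1, 5, 0, 2, 4])
        permuted = model.infer(images[perm]).y.data
        np.testing.assert_array_equal(full[perm], permuted)

    def test_trace_shape_contracts(self, tiny_net_config, tiny_scenes):
        model = HTDANetwork(tiny_net_config, rng=2)
        images = tiny_scenes[0][:3]
        trace = model.infer(images, collect=True)
        k = tiny_net_config.k_steps
        assert len(trace.logits) == k
        assert trace.y.shape == (3, tiny_net_config.n_classes)
        assert len(trace.map_indices) == k
        for name, steps in trace.spikes.items():
            assert len(steps) == k
            for s in steps:
                assert set(np.unique(s)) <= {0, 1}

    def test_dynamic_mode_frame_count_checked(self):
        cfg = NetworkConfig(
            height=16, width=16, in_channels=2, base_channels=4, n_classes=2,
            hidden=16, k_steps=4, mode="dynamic",
        )
        model = HTDANetwork(cfg, rng=0)
        with pytest.raises(ValueError):
            model.infer(np.zeros((3, 2, 2, 16, 16)))  # K mismatch

    def test_dynamic_mode_regenerates_maps(self):
        cfg = NetworkConfig(
            height=16, width=16, in_channels=2, base_channels=4, n_classes=2,
            hidden=16, k_steps=6, mode="dynamic",
        )
        model = HTDANetwork(cfg, rng=0)
        rng = np.random.default_rng(0)
        frames = (rng.uniform(size=(6, 2, 2, 16, 16)) > 0.7).astype(float)
        trace = model.infer(frames)
        assert trace.map_indices == [0, 0, 1, 1, 2, 2]
        assert sorted(trace.maps) == [0, 1, 2]


class TestConfigValidation:
    def test_tf_must_be_multiple_of_td(self):
        with pytest.raises(ValueError):
            NetworkConfig(tf=1.5, td=1.0)

    def test_k_must_cover_a_window(self):
        with pytest.raises(ValueError):
            NetworkConfig(k_steps=1, tf=2.0, td=1.0)
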