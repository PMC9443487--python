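"""Synthetic scenes, perturbations, event streams, accumulation, N-MNIST format."""

import io

import numpy as np
import pytest

from htda.data import (
    EventStream,
    accumulate_events,
    gen_moving_events,
    gen_static_scene,
    make_event_dataset,
    make_scene_dataset,
    perturb_scene,
    read_nmnist,
    write_nmnist,
)


class TestStaticScenes:
    def test_deterministic_per_seed(self):
        a = gen_static_scene(0, seed=42)
        b = gen_static_scene(0, seed=42)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)
        c = gen_static_scene(0, seed=43)
        assert not np.array_equal(a.image, c.image)

    @pytest.mark.parametrize("label_mode", ["shape", "texture"])
    def test_mask_fraction_band(self, label_mode):
        margin = 0.25 if label_mode == "shape" else 0.10
        for seed in range(100):
            s = gen_static_scene(seed % 3 if label_mode == "shape" else seed % 2,
                                 seed=seed, label_mode=label_mode, contrast_margin=margin)
            frac = s.mask.mean()
            assert 0.10 <= frac <= 0.25, f"seed {seed}: fraction {frac}"

    def test_object_background_contrast(self):
        for seed in range(30):
            s = gen_static_scene(seed % 3, seed=seed)
            on = s.image[:, s.mask].mean()
            off = s.image[:, ~s.mask].mean()
            assert on - off >= 0.25

    def test_values_in_unit_interval(self):
        s = gen_static_scene(1, seed=5, n_channels=3)
        assert s.image.shape == (3, 16, 16)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            gen_static_scene(7, seed=0)

    def test_texture_mode_silhouette_uninformative(self):
        # both texture classes use the same (disk) silhouette family; the
        # stripe orientation differs inside the object
        a = gen_static_scene(0, seed=1, label_mode="texture", contrast_margin=0.1)
        b = gen_static_scene(1, seed=1, label_mode="texture", contrast_margin=0.1)
        img_a, img_b = a.image[0], b.image[0]
        # horizontal stripes: rows constant inside the object; vertical: columns
        row_var = np.var([img_a[r, a.mask[r]].std() for r in range(16) if a.mask[r].sum() > 2])
        assert row_var < 0.05  # class-0 rows are flat inside the mask

    def test_dataset_batch_shapes_and_balance(self):
        images, labels, masks = make_scene_dataset(10, classes=(0, 1), size=16, seed=0)
        assert images.shape == (10, 1, 16, 16)
        assert masks.shape == (10, 16, 16)
        assert set(labels) == {0, 1} and labels.sum() == 5


class TestPerturbScene:
    def test_zero_magnitude_identity(self):
        s = gen_static_scene(0, seed=3)
        t = perturb_scene(s, "translate", (0, 0))
        np.testing.assert_array_equal(t.image, s.image)
        r = perturb_scene(s, "rotate", 0.0)
        np.testing.assert_allclose(r.image, s.image, atol=1e-12)

    def test_translation_moves_mask_centroid(self):
        s = gen_static_scene(0, seed=8)
        dx, dy = 2, -1
        t = perturb_scene(s, "translate", (dx, dy))
        # the object sits interior for this seed: no border clipping
        assert t.mask.sum() == s.mask.sum()
        cy0, cx0 = np.argwhere(s.mask).mean(axis=0)
        cy1, cx1 = np.argwhere(t.mask).mean(axis=0)
        assert (cx1 - cx0, cy1 - cy0) == (dx, dy)

    def test_gaussian_noise_statistics(self):
        s = gen_static_scene(0, seed=3)
        flat = s
        flat.image[:] = 0.5  # flat field isolates the added noise
        sigma = 0.05
        t = perturb_scene(flat, "gaussian", sigma, seed=1)
        np.testing.assert_array_equal(t.mask, s.mask)  # noise leaves the mask alone
        noise = t.image - 0.5
        assert abs(noise.std() - sigma) / sigma < 0.10

    def test_translate_composition(self):
        s = gen_static_scene(0, seed=8)
        one = perturb_scene(perturb_scene(s, "translate", (1, 0)), "translate", (1, 1))
        two = perturb_scene(s, "translate", (2, 1))
        np.testing.assert_array_equal(one.mask, two.mask)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            perturb_scene(gen_static_scene(0, seed=0), "shear", 1.0)


class TestMovingEvents:
    def test_zero_velocity_empty_stream(self):
        s = gen_moving_events(0, duration_ms=20, seed=0, speed_px_per_ms=0.0)
        assert len(s) == 0

    def test_coordinates_within_bounds(self):
        s = gen_moving_events(1, sensor_size=(16, 16), duration_ms=50, seed=3)
        assert len(s) > 0
        assert s.x.min() >= 0 and s.x.max() < 16
        assert s.y.min() >= 0 and s.y.max() < 16
        assert np.all(np.diff(s.t) >= 0)

    def test_centroid_drifts_monotonically(self):
        # accumulate frames and regress the occupancy centroid on time
        s = gen_moving_events(0, sensor_size=(16, 16), duration_ms=50, seed=1,
                              speed_px_per_ms=0.25, thinning=1.0)
        frames = accumulate_events(s, bin_ms=5.0, num_steps=10, clip_binary=True)
        occ = frames.sum(axis=1)  # (steps, H, W)
        cents = []
        for f in occ:
            ys, xs = np.nonzero(f)
            if len(xs):
                cents.append((xs.mean(), ys.mean()))
        cents = np.array(cents)
        disp = np.linalg.norm(cents[-1] - cents[0])
        assert len(cents) >= 5 and disp > 1.0  # sustained drift along the path


class TestAccumulateEvents:
    def test_empty_stream_zero_frames(self):
        s = EventStream(*(np.empty(0, dtype=np.int64),) * 4, sensor_size=(8, 8))
        frames = accumulate_events(s, bin_ms=5.0, num_steps=4)
        assert frames.shape == (4, 2, 8, 8) and frames.sum() == 0

    def test_single_event_binning(self):
        s = EventStream(
            t=np.array([3000]), x=np.array([2]), y=np.array([5]),
            polarity=np.array([1]), sensor_size=(8, 8),
        )
        frames = accumulate_events(s, bin_ms=5.0, num_steps=2)
        assert frames[0, 1, 5, 2] == 1.0
        assert frames.sum() == 1.0

    def test_matches_per_event_loop_oracle(self, rng):
        n = 300
        t = np.sort(rng.integers(0, 60_000, size=n))
        x = rng.integers(0, 8, size=n)
        y = rng.integers(0, 8, size=n)
        pol = rng.integers(0, 2, size=n)
        s = EventStream(t=t, x=x, y=y, polarity=pol, sensor_size=(8, 8))
        frames = accumulate_events(s, bin_ms=5.0, num_steps=10, clip_binary=False)
        want = np.zeros((10, 2, 8, 8))
        for ti, xi, yi, pi in zip(t, x, y, pol):
            b = int(ti // 5000)
            if b < 10:
                want[b, pi, yi, xi] += 1
        np.testing.assert_array_equal(frames, want)
        # count conservation: in-window events all land in some bin
        assert frames.sum() == (t < 50_000).sum()

    def test_binary_clipping(self):
        s = EventStream(
            t=np.array([0, 1, 2]), x=np.array([1, 1, 1]), y=np.array([1, 1, 1]),
            polarity=np.array([1, 1, 1]), sensor_size=(4, 4),
        )
        raw = accumulate_events(s, bin_ms=1.0, num_steps=1, clip_binary=False)
        assert raw[0, 1, 1, 1] == 3.0
        clipped = accumulate_events(s, bin_ms=1.0, num_steps=1, clip_binary=True)
        assert clipped[0, 1, 1, 1] == 1.0

    def test_event_dataset_shapes(self):
        frames, labels = make_event_dataset(4, num_steps=10, seed=0)
        assert frames.shape == (4, 10, 2, 16, 16)
        assert set(np.unique(frames)) <= {0.0, 1.0}
        assert labels.tolist() == [0, 1, 0, 1]


class TestNMNISTFormat:
    def test_crafted_single_record(self):
        # x=5, y=7, ON, t=1000 us
        t = 1000
        rec = bytes([5, 7, (1 << 7) | ((t >> 16) & 0x7F), (t >> 8) & 0xFF, t & 0xFF])
        s = read_nmnist(rec)
        assert len(s) == 1
        assert (s.x[0], s.y[0], s.polarity[0], s.t[0]) == (5, 7, 1, 1000)

    def test_roundtrip_synthetic_stream(self):
        stream = gen_moving_events(0, sensor_size=(16, 16), duration_ms=30, seed=2)
        buf = io.BytesIO()
        write_nmnist(stream, buf)
        back = read_nmnist(buf.getvalue(), sensor_size=(16, 16))
        np.testing.assert_array_equal(back.t, stream.t)
        np.testing.assert_array_equal(back.x, stream.x)
        np.testing.assert_array_equal(back.y, stream.y)
        np.testing.assert_array_equal(back.polarity, stream.polarity)

    def test_record_count_is_size_over_five(self, rng, tmp_path):
        stream = gen_moving_events(1, duration_ms=25, seed=4)
        path = tmp_path / "events.bin"
        write_nmnist(stream, str(path))
        assert path.stat().st_size == 5 * len(stream)
        assert len(read_nmnist(str(path), sensor_size=(16, 16))) == len(stream)

    def test_truncated_record_rejected_with_offset(self):
        with pytest.raises(ValueError, match="offset"):
            read_nmnist(bytes(7))
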