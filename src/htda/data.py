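"""Synthetic scenes, event streams, perturbations, and the N-MNIST binary reader.

Static scenes emulate object-on-textured-background recognition: a class-
determined shape (disk, cross, bar) at a random pose over a smooth textured
background, with the ground-truth object mask kept alongside.  Object
pixels are bright (0.75-0.95) and background dim (0.05-0.45), so the
object/background contrast margin is at least 0.3 by construction, and the
shape size is drawn so the mask covers 10-25% of pixels.

Event streams emulate a moving object seen by a dynamic vision sensor: the
shape translates along a seeded straight path; newly covered pixels emit ON
events, newly uncovered pixels OFF events, each kept with a thinning
probability (Bernoulli, emulating sensor unreliability).  Frames are
accumulated over half-open time bins [s*bin, (s+1)*bin) into
(steps, 2, H, W) count tensors, clipped to {0,1} by default (binary spikes
at the sensor); raw counts are available for the attack path.

Coordinates are 0-based, row-major, origin top-left.  All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

SHAPE_CLASSES = ("disk", "cross", "bar")


@dataclass
class ToyScene:
    image: np.ndarray  # (C, H, W) in [0,1]
    mask: np.ndarray  # (H, W) bool, object support
    label: int
    seed: int


@dataclass
class EventStream:
    t: np.ndarray  # microseconds, non-decreasing
    x: np.ndarray  # column index
    y: np.ndarray  # row index
    polarity: np.ndarray  # 1 = ON, 0 = OFF
    sensor_size: tuple[int, int]  # (H, W)

    def __post_init__(self):
        if len(self.t) and np.any(np.diff(self.t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        h, w = self.sensor_size
        if len(self.t) and (self.x.min() < 0 or self.x.max() >= w or self.y.min() < 0 or self.y.max() >= h):
            raise ValueError("event coordinates outside sensor bounds")

    def __len__(self) -> int:
        return len(self.t)


# -- static scenes -------------------------------------------------------------


def _draw_shape(kind: str, size: int, rng: np.random.Generator, frac_lo: float, frac_hi: float) -> np.ndarray:
    """Binary mask of one shape at a random pose with area fraction in band."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    for _ in range(64):
        frac = rng.uniform(frac_lo, frac_hi)
        cy = rng.uniform(0.3 * size, 0.7 * size)
        cx = rng.uniform(0.3 * size, 0.7 * size)
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = ct * (xx - cx) + st * (yy - cy)
        v = -st * (xx - cx) + ct * (yy - cy)
        if kind == "disk":
            r = np.sqrt(frac * size * size / np.pi)
            mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        elif kind == "cross":
            # two orthogonal arms, width w, length L: area ~ 2wL - w^2
            length = 0.8 * size
            wdt = max((frac * size * size) / (2 * length), 1.2)
            mask = ((np.abs(u) <= wdt / 2) & (np.abs(v) <= length / 2)) | (
                (np.abs(v) <= wdt / 2) & (np.abs(u) <= length / 2)
            )
        elif kind == "bar":
            length = 0.85 * size
            wdt = max(frac * size * size / length, 1.2)
            mask = (np.abs(u) <= wdt / 2) & (np.abs(v) <= length / 2)
        else:
            raise ValueError(f"unknown shape class {kind!r}")
        got = mask.mean()
        if frac_lo <= got <= frac_hi:
            return mask
    return mask  # last attempt; band violations are caught by tests on defaults


STRIPE_AXES = ("rows", "cols", "diag")  # texture-label stripe orientations per class


def gen_static_scene(
    class_index: int,
    size: int = 16,
    seed: int = 0,
    n_channels: int = 1,
    mask_frac: tuple[float, float] = (0.10, 0.25),
    contrast_margin: float = 0.25,
    label_mode: str = "shape",
) -> ToyScene:
    """One textured scene with a class-determined object and its ground-truth mask.

    `label_mode="shape"`: the class picks the silhouette (disk/cross/bar) and
    the interior is unstructured bright texture.  `label_mode="texture"`: all
    classes share a compact disk silhouette and the class picks the
    orientation of a high-contrast square-wave stripe grating filling the
    object — then the label is unrecoverable from the silhouette alone, so
    only the object's interior (not its outline) is informative.
    """
    if not (0 <= class_index < len(SHAPE_CLASSES)):
        raise ValueError(f"class index must be in [0,{len(SHAPE_CLASSES)}), got {class_index}")
    if label_mode not in ("shape", "texture"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    rng = np.random.default_rng([seed, class_index])
    background = ndimage.gaussian_filter(rng.uniform(0.0, 1.0, size=(size, size)), sigma=2.0)
    lo, hi = background.min(), background.max()
    background = 0.05 + 0.40 * (background - lo) / max(hi - lo, 1e-12)
    kind = SHAPE_CLASSES[class_index] if label_mode == "shape" else "disk"
    mask = _draw_shape(kind, size, rng, *mask_frac)
    if label_mode == "shape":
        obj = rng.uniform(0.75, 0.95, size=(size, size))
    else:
        axis = STRIPE_AXES[class_index]
        offset = int(rng.integers(0, 2))
        yy, xx = np.mgrid[0:size, 0:size]
        coord = {"rows": yy, "cols": xx, "diag": xx + yy}[axis] + offset
        obj = np.where(coord % 2 == 0, 0.95, 0.15)  # period-2 square wave
    img = np.where(mask, obj, background)
    image = np.broadcast_to(img, (n_channels, size, size)).copy()
    if n_channels > 1:  # slight per-channel tint keeps channels informative
        tint = rng.uniform(0.9, 1.0, size=(n_channels, 1, 1))
        image = np.clip(image * tint, 0.0, 1.0)
    on = image[:, mask].mean()
    off = image[:, ~mask].mean()
    if on - off < contrast_margin:
        raise RuntimeError(f"generated scene violates contrast margin: {on - off:.3f}")
    return ToyScene(image=image, mask=mask, label=class_index, seed=seed)


def perturb_scene(scene: ToyScene, kind: str, magnitude, seed: int = 0) -> ToyScene:
    """Translated, rotated or Gaussian-noised copy; the mask tracks geometry."""
    rng = np.random.default_rng([seed, 97])
    img, mask = scene.image, scene.mask
    if kind == "translate":
        dx, dy = (magnitude if np.iterable(magnitude) else (magnitude, magnitude))
        dx, dy = int(dx), int(dy)
        out = np.zeros_like(img)
        mout = np.zeros_like(mask)
        h, w = mask.shape
        ys, ye = max(dy, 0), min(h + dy, h)
        xs, xe = max(dx, 0), min(w + dx, w)
        out[:, ys:ye, xs:xe] = img[:, ys - dy : ye - dy, xs - dx : xe - dx]
        mout[ys:ye, xs:xe] = mask[ys - dy : ye - dy, xs - dx : xe - dx]
        img, mask = out, mout
    elif kind == "rotate":
        angle = float(magnitude)
        img = np.stack(
            [ndimage.rotate(ch, angle, reshape=False, order=1, mode="nearest") for ch in img]
        )
        mask = ndimage.rotate(mask.astype(np.float64), angle, reshape=False, order=0, mode="constant") > 0.5
    elif kind == "gaussian":
        img = img + rng.normal(0.0, float(magnitude), size=img.shape)
    else:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return ToyScene(image=np.clip(img, 0.0, 1.0), mask=mask, label=scene.label, seed=scene.seed)


def make_scene_dataset(
    n: int,
    classes: tuple[int, ...] = (0, 1),
    size: int = 16,
    seed: int = 0,
    n_channels: int = 1,
    label_mode: str = "shape",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(images (n,C,H,W), labels (n,), masks (n,H,W)) with balanced classes."""
    rng = np.random.default_rng(seed)
    images = np.empty((n, n_channels, size, size))
    labels = np.empty(n, dtype=np.int64)
    masks = np.empty((n, size, size), dtype=bool)
    # striped interiors average darker than a solid bright fill, so the
    # guaranteed mean-contrast margin is smaller in texture mode
    margin = 0.25 if label_mode == "shape" else 0.10
    for i in range(n):
        cls = classes[i % len(classes)]
        s = int(rng.integers(0, 2**31 - 1))
        scene = gen_static_scene(
            cls, size=size, seed=s, n_channels=n_channels, label_mode=label_mode,
            contrast_margin=margin,
        )
        images[i] = scene.image
        labels[i] = classes.index(cls)
        masks[i] = scene.mask
    return images, labels, masks


# -- event streams -------------------------------------------------------------


def gen_moving_events(
    class_index: int,
    sensor_size: tuple[int, int] = (16, 16),
    duration_ms: float = 50.0,
    seed: int = 0,
    dt_ms: float = 1.0,
    speed_px_per_ms: float | None = None,
    thinning: float = 0.6,
) -> EventStream:
    """Events from a shape translating along a seeded straight path.

    Newly covered pixels emit ON events, newly uncovered pixels OFF events;
    each event is kept with probability `thinning`.  Zero speed yields an
    empty stream (no edges move).
    """
    h, w = sensor_size
    rng = np.random.default_rng([seed, class_index, 7])
    shape_mask = _draw_shape(SHAPE_CLASSES[class_index], min(h, w), rng, 0.10, 0.25)
    if speed_px_per_ms is None:
        speed_px_per_ms = rng.uniform(0.15, 0.3)
    angle = rng.uniform(0.0, 2 * np.pi)
    vx, vy = speed_px_per_ms * np.cos(angle), speed_px_per_ms * np.sin(angle)
    n_frames = int(np.floor(duration_ms / dt_ms))
    ts, xs, ys, ps = [], [], [], []

    def render(t_ms: float) -> np.ndarray:
        dx, dy = int(round(vx * t_ms)), int(round(vy * t_ms))
        out = np.zeros((h, w), dtype=bool)
        # wrap the path so the object stays on-sensor over long durations
        rolled = np.roll(np.roll(shape_mask, dy % h, axis=0), dx % w, axis=1)
        out[: rolled.shape[0], : rolled.shape[1]] = rolled
        return out

    prev = render(0.0)
    for f in range(1, n_frames + 1):
        cur = render(f * dt_ms)
        on_y, on_x = np.nonzero(cur & ~prev)
        off_y, off_x = np.nonzero(prev & ~cur)
        for (py, px, pol) in ((on_y, on_x, 1), (off_y, off_x, 0)):
            keep = rng.uniform(size=len(py)) < thinning
            py, px = py[keep], px[keep]
            jitter = rng.uniform(0.0, dt_ms * 1000.0, size=len(py))
            ts.append((f - 1) * dt_ms * 1000.0 + jitter)
            xs.append(px)
            ys.append(py)
            ps.append(np.full(len(py), pol, dtype=np.int64))
        prev = cur
    if ts:
        t = np.concatenate(ts)
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        p = np.concatenate(ps)
        order = np.argsort(t, kind="stable")
        return EventStream(
            t=t[order].astype(np.int64), x=x[order], y=y[order], polarity=p[order], sensor_size=sensor_size
        )
    empty = np.empty(0, dtype=np.int64)
    return EventStream(t=empty, x=empty.copy(), y=empty.copy(), polarity=empty.copy(), sensor_size=sensor_size)


def accumulate_events(
    stream: EventStream, bin_ms: float = 5.0, num_steps: int = 10, clip_binary: bool = True
) -> np.ndarray:
    """(steps, 2, H, W) per-polarity counts over half-open bins [s*bin, (s+1)*bin).

    Events beyond the last bin are dropped.  Channel 0 is OFF, channel 1 ON.
    With `clip_binary` counts are clipped to {0,1} (binary sensor spikes).
    """
    if bin_ms <= 0 or num_steps < 1:
        raise ValueError("bin width must be positive and num_steps >= 1")
    h, w = stream.sensor_size
    frames = np.zeros((num_steps, 2, h, w))
    if len(stream):
        bin_us = bin_ms * 1000.0
        s = np.floor(stream.t / bin_us).astype(np.int64)
        ok = (s >= 0) & (s < num_steps)
        np.add.at(frames, (s[ok], stream.polarity[ok], stream.y[ok], stream.x[ok]), 1.0)
    if clip_binary:
        frames = np.clip(frames, 0.0, 1.0)
    return frames


def make_event_dataset(
    n: int,
    classes: tuple[int, ...] = (0, 1),
    sensor_size: tuple[int, int] = (16, 16),
    num_steps: int = 10,
    bin_ms: float = 5.0,
    seed: int = 0,
    clip_binary: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(frames (n, steps, 2, H, W), labels (n,)) from seeded moving-object streams."""
    rng = np.random.default_rng(seed)
    frames = np.empty((n, num_steps, 2, *sensor_size))
    labels = np.empty(n, dtype=np.int64)
    duration = bin_ms * num_steps
    for i in range(n):
        cls = classes[i % len(classes)]
        s = int(rng.integers(0, 2**31 - 1))
        stream = gen_moving_events(cls, sensor_size=sensor_size, duration_ms=duration, seed=s)
        frames[i] = accumulate_events(stream, bin_ms=bin_ms, num_steps=num_steps, clip_binary=clip_binary)
        labels[i] = classes.index(cls)
    return frames, labels


# -- N-MNIST binary dialect ----------------------------------------------------


def read_nmnist(source, sensor_size: tuple[int, int] = (34, 34)) -> EventStream:
    """Decode the 5-byte-per-event binary layout.

    Byte 0: x, byte 1: y, byte 2 bit 7: polarity (1 = ON), remaining 23 bits
    of bytes 2-4: timestamp in microseconds.  Events are returned sorted by
    timestamp.
    """
    if isinstance(source, bytes):
        raw = source
    elif hasattr(source, "read"):
        raw = source.read()
    else:
        with open(source, "rb") as fh:
            raw = fh.read()
    if len(raw) % 5:
        raise ValueError(
            f"truncated record: file length {len(raw)} is not a multiple of 5 "
            f"(offset of partial record: {len(raw) - len(raw) % 5})"
        )
    arr = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 5).astype(np.int64)
    x = arr[:, 0]
    y = arr[:, 1]
    pol = (arr[:, 2] >> 7) & 1
    t = ((arr[:, 2] & 0x7F) << 16) | (arr[:, 3] << 8) | arr[:, 4]
    order = np.argsort(t, kind="stable")
    return EventStream(t=t[order], x=x[order], y=y[order], polarity=pol[order], sensor_size=sensor_size)


def write_nmnist(stream: EventStream, target) -> None:
    """Inverse of read_nmnist (round-trips any in-range stream)."""
    if len(stream) and (stream.t.max() >= 1 << 23 or stream.x.max() > 255 or stream.y.max() > 255):
        raise ValueError("stream exceeds the 5-byte record ranges (23-bit t, 8-bit x/y)")
    out = np.empty((len(stream), 5), dtype=np.uint8)
    out[:, 0] = stream.x
    out[:, 1] = stream.y
    out[:, 2] = ((stream.polarity & 1) << 7) | ((stream.t >> 16) & 0x7F)
    out[:, 3] = (stream.t >> 8) & 0xFF
    out[:, 4] = stream.t & 0xFF
    data = out.tobytes()
    if hasattr(target, "write"):
        target.write(data)
    else:
        with open(target, "wb") as fh:
            fh.write(data)
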