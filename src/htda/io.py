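"""Checkpoint and map export: single-file archives of named arrays + config.

A checkpoint is an .npz archive holding every parameter array (trainable or
frozen) plus a JSON-encoded configuration block, so a model reloads without
any out-of-band information.  Attention maps export as 8-bit grayscale PNGs
(value = round(255 * gate)) for visual inspection.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .network import HTDANetwork, NetworkConfig


def save_checkpoint(model: HTDANetwork, path: str, extra: dict | None = None) -> None:
    arrays = model.state_arrays()
    meta = {"config": dataclasses.asdict(model.config), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str) -> HTDANetwork:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    config = NetworkConfig(**meta["config"])
    model = HTDANetwork(config, rng=0)
    model.load_state_arrays(arrays)
    return model


def export_map_png(map_values: np.ndarray, path: str) -> None:
    """Write a gate matrix in [0,1] as an 8-bit grayscale PNG."""
    from matplotlib import image as mpimg

    arr = np.asarray(map_values, dtype=np.float64)
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a single 2-D map, got shape {arr.shape}")
    mpimg.imsave(path, np.round(255.0 * arr).astype(np.uint8), cmap="gray", vmin=0, vmax=255)
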