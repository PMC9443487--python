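"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive — per-neuron scalar loops, explicit
four-deep convolution loops — so they share no code path with the
vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# -- independent reference implementations ------------------------------------


def scalar_lif_trace(drives, lam, v_th):
    """Per-neuron scalar LIF loop: returns the spike train for one neuron.

    drives: 1-D sequence of per-step synaptic drive for a single neuron.
    """
    h = 0.0
    o = 0.0
    spikes = []
    for i_k in drives:
        h = h * lam * (1.0 - o) + i_k
        o = 1.0 if h >= v_th else 0.0
        spikes.append(o)
    return spikes


def loop_conv2d(x, w, b=None, padding=0):
    """Explicit-loop 2-D cross-correlation, NCHW; zero padding."""
    n, cin, h, wd = x.shape
    cout, _, kh, kw = w.shape
    p = padding
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho, wo = h + 2 * p - kh + 1, wd + 2 * p - kw + 1
    out = np.zeros((n, cout, ho, wo))
    for nn in range(n):
        for co in range(cout):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(cin):
                        for a in range(kh):
                            for bb in range(kw):
                                acc += xp[nn, ci, i + a, j + bb] * w[co, ci, a, bb]
                    out[nn, co, i, j] = acc + (b[co] if b is not None else 0.0)
    return out


def loop_conv_transpose2d(x, w, stride=2, padding=1):
    """Explicit-loop transposed convolution; w is (C_in, C_out, kh, kw)."""
    n, cin, h, wd = x.shape
    _, cout, kh, kw = w.shape
    ho = (h - 1) * stride - 2 * padding + kh
    wo = (wd - 1) * stride - 2 * padding + kw
    out = np.zeros((n, cout, ho, wo))
    for nn in range(n):
        for ci in range(cin):
            for i in range(h):
                for j in range(wd):
                    v = x[nn, ci, i, j]
                    for co in range(cout):
                        for a in range(kh):
                            for bb in range(kw):
                                oi = i * stride - padding + a
                                oj = j * stride - padding + bb
                                if 0 <= oi < ho and 0 <= oj < wo:
                                    out[nn, co, oi, oj] += v * w[ci, co, a, bb]
    return out


def loop_high_pass_l1(m, stencil):
    """|M (*) K| summed, replicate boundary, explicit loops; m is 2-D."""
    h, w = m.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in (-1, 0, 1):
                for b in (-1, 0, 1):
                    ii = min(max(i + a, 0), h - 1)
                    jj = min(max(j + b, 0), w - 1)
                    acc += m[ii, jj] * stencil[a + 1, b + 1]
            total += abs(acc)
    return total


def numeric_grad(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


# -- fixtures ------------------------------------------------------------------


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_net_config():
    from htda.network import NetworkConfig

    return NetworkConfig(
        height=16, width=16, in_channels=1, base_channels=4, n_classes=2,
        hidden=32, k_steps=4, mode="static",
    )


@pytest.fixture(scope="session")
def tiny_scenes():
    from htda.data import make_scene_dataset

    return make_scene_dataset(40, seed=7, label_mode="texture")
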