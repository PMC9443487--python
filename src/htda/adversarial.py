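"""L-infinity projected gradient descent (PGD) attack through the full model.

    X_0     = clip(X + Uniform(-eps, eps))
    X_{i+1} = Proj[ X_i + eta * sgn(grad_X CE(Y(X_i), label)) ]

The gradient is taken through the complete unrolled closed loop — the
attention generator and gating are part of the attacked graph, not frozen.
Proj intersects the eps-ball around the clean input with the valid input
interval (default [0,1]) and is applied after every iteration, so the
budget bound holds throughout, not just at return.  The attacked loss is
the classification cross-entropy on the decoded prediction Y (robustness
is defined on predictions).

For event data the attack perturbs the real-valued accumulated frame
tensors directly; the noise is real-valued, never re-binarized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .network import HTDANetwork
from .objectives import classification_loss


@dataclass
class PGDConfig:
    epsilon: float = 8 / 255  # L-inf budget, input-intensity units
    eta: float | None = None  # step size; defaults to epsilon/4
    iterations: int = 10
    clip_min: float = 0.0
    clip_max: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.iterations < 0:
            raise ValueError("iteration count must be non-negative")
        if self.eta is None:
            self.eta = self.epsilon / 4.0
        if self.iterations > 0 and self.epsilon > 0 and self.eta <= 0:
            raise ValueError("step size must be positive")


def _project(x: np.ndarray, x_clean: np.ndarray, cfg: PGDConfig) -> np.ndarray:
    x = np.clip(x, x_clean - cfg.epsilon, x_clean + cfg.epsilon)
    return np.clip(x, cfg.clip_min, cfg.clip_max)


def _input_gradient(model: HTDANetwork, x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    xt = Tensor(x, requires_grad=True)
    trace = model.infer(xt, collect=False)
    loss = classification_loss(trace.y, labels)
    loss.backward()
    return xt.grad


def pgd_attack(
    model: HTDANetwork,
    x: np.ndarray,
    labels: np.ndarray,
    config: PGDConfig,
) -> np.ndarray:
    """Adversarial inputs within the eps-ball of `x`, gradients through the closed loop.

    `x` is (N, C, H, W) in static mode or (K, N, C, H, W) accumulated frames
    in dynamic mode; `labels` are the true classes (the attacked loss
    ascends CE against them).
    """
    x = np.asarray(x, dtype=np.float64)
    labels = np.asarray(labels)
    if config.epsilon == 0.0:
        return x.copy()
    rng = np.random.default_rng(config.seed)
    adv = _project(x + rng.uniform(-config.epsilon, config.epsilon, size=x.shape), x, config)
    for _ in range(config.iterations):
        g = _input_gradient(model, adv, labels)
        adv = _project(adv + config.eta * np.sign(g), x, config)
    return adv


def attack_event_frames(
    model: HTDANetwork,
    frames: np.ndarray,
    labels: np.ndarray,
    config: PGDConfig,
) -> np.ndarray:
    """PGD on accumulated (real-valued) event frames; identical update rule."""
    frames = np.asarray(frames, dtype=np.float64)
    if model.config.mode != "dynamic":
        raise ValueError("attack_event_frames expects a dynamic-mode model")
    return pgd_attack(model, frames, labels, config)


def robust_accuracy(
    model: HTDANetwork,
    images: np.ndarray,
    labels: np.ndarray,
    config: PGDConfig,
    batch_size: int = 100,
) -> float:
    """Fraction of attacked samples still classified correctly."""
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("robust_accuracy needs a non-empty dataset")
    dynamic = model.config.mode == "dynamic"
    correct = 0
    for start in range(0, n, batch_size):
        sl = slice(start, start + batch_size)
        batch = images[:, sl] if dynamic else images[sl]
        yb = labels[sl]
        adv = pgd_attack(model, batch, yb, config)
        trace = model.infer(adv, collect=False)
        correct += int((trace.prediction == yb).sum())
    return correct / n
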