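"""Joint end-to-end training of the unrolled closed-loop model.

Optimization is mini-batch SGD with momentum (default 0.9) on the joint
objective L = alpha*L_C + (1-alpha)*L_M, backpropagated through the full
K-step unrolled graph including the attention feedback (no stop-gradient
anywhere).  The learning rate ramps linearly from 10% of its initial value
over the first warm-up epochs; the sigmoid temperature of the attention
generator anneals from 1 to its maximum over the configured span.  A fixed
seed governs weight initialization and batch shuffling, so single-threaded
runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .attention import TemperatureSchedule
from .autodiff import Tensor
from .network import HTDANetwork
from .objectives import HighPassKernel, LossWeights, attention_loss, classification_loss, total_loss


@dataclass
class TrainConfig:
    epochs: int = 60
    batch_size: int = 200
    lr: float = 0.1
    momentum: float = 0.9
    warmup_epochs: int = 5
    warmup_start_frac: float = 0.1
    lr_decay: str | None = None  # None or "cosine"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    temperature: TemperatureSchedule | None = None
    seed: int = 0
    stop_at_train_acc: float | None = None  # early exit once reached (epoch granularity)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warm-up must be shorter than the run")
        if self.temperature is None:
            self.temperature = TemperatureSchedule(span=max(int(0.8 * self.epochs), 1))


def sgd_momentum_step(
    param: np.ndarray, grad: np.ndarray, velocity: np.ndarray, lr: float, momentum: float
) -> tuple[np.ndarray, np.ndarray]:
    """v' = momentum*v + g;  p' = p - lr*v'."""
    if param.shape != grad.shape or param.shape != velocity.shape:
        raise ValueError("param/grad/velocity shapes must match")
    v_new = momentum * velocity + grad
    return param - lr * v_new, v_new


def warmup_lr(epoch: int, config: TrainConfig) -> float:
    """Linear ramp from warmup_start_frac*lr to lr, then flat (or cosine decay)."""
    if epoch < 0:
        raise ValueError("epoch index must be >= 0")
    lr0 = config.lr
    if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
        f0 = config.warmup_start_frac
        return lr0 * (f0 + (1.0 - f0) * epoch / config.warmup_epochs)
    if config.lr_decay == "cosine":
        span = max(config.epochs - config.warmup_epochs, 1)
        t = (epoch - config.warmup_epochs) / span
        return lr0 * 0.5 * (1.0 + math.cos(math.pi * min(t, 1.0)))
    return lr0


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    temperature: float
    loss: float
    loss_c: float
    loss_m: float
    train_acc: float


class SGDMomentum:
    def __init__(self, params: dict, momentum: float):
        self.momentum = momentum
        self.velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, params: dict, lr: float) -> None:
        for k, p in params.items():
            if p.grad is None:
                continue
            p.data, self.velocity[k] = sgd_momentum_step(
                p.data, p.grad, self.velocity[k], lr, self.momentum
            )


def train(
    model: HTDANetwork,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    kernel: HighPassKernel | None = None,
    verbose: bool = False,
) -> list[EpochRecord]:
    """Train in place; returns the per-epoch history of loss terms and accuracy.

    `images` is (N, C, H, W) for static mode or (N, K, C, H, W) for dynamic
    mode (per-sample frame sequences); `labels` is (N,) class indices.
    """
    rng = np.random.default_rng(config.seed)
    params = model.params()
    opt = SGDMomentum(params, config.momentum)
    kernel = kernel or HighPassKernel()
    n = images.shape[0]
    dynamic = model.config.mode == "dynamic"
    history: list[EpochRecord] = []
    for epoch in range(config.epochs):
        lr = warmup_lr(epoch, config)
        te = config.temperature(epoch, training=True)
        order = rng.permutation(n)
        tot_l = tot_lc = tot_lm = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = images[idx]
            if dynamic:
                batch = np.swapaxes(batch, 0, 1)  # -> (K, B, C, H, W)
            yb = labels[idx]
            trace = model.infer(batch, te=te, collect=False)
            l_c = classification_loss(trace.y, yb)
            gen_maps = trace.generated_maps()
            if model.config.attention and gen_maps:
                l_m = attention_loss(gen_maps, config.loss_weights, kernel)
            else:
                l_m = Tensor(0.0)
            loss = total_loss(l_c, l_m, config.loss_weights.alpha)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={float(loss.data)} "
                    f"(L_C={float(l_c.data)}, L_M={float(l_m.data)})"
                )
            for p in params.values():
                p.zero_grad()
            loss.backward()
            opt.step(params, lr)
            bsz = len(idx)
            tot_l += float(loss.data) * bsz
            tot_lc += float(l_c.data) * bsz
            tot_lm += float(l_m.data) * bsz
            correct += int((trace.prediction == yb).sum())
        rec = EpochRecord(
            epoch=epoch, lr=lr, temperature=te,
            loss=tot_l / n, loss_c=tot_lc / n, loss_m=tot_lm / n,
            train_acc=correct / n,
        )
        history.append(rec)
        if verbose:
            print(
                f"epoch {epoch:3d}  lr {lr:.4f}  Te {te:.2f}  "
                f"loss {rec.loss:.4f} (C {rec.loss_c:.4f}, M {rec.loss_m:.4f})  "
                f"acc {rec.train_acc:.3f}"
            )
        if config.stop_at_train_acc is not None and rec.train_acc >= config.stop_at_train_acc:
            break
    return history


def evaluate_accuracy(model: HTDANetwork, images: np.ndarray, labels: np.ndarray, batch_size: int = 200) -> float:
    """Clean accuracy of argmax(Y) at the inference-phase temperature."""
    n = images.shape[0]
    dynamic = model.config.mode == "dynamic"
    correct = 0
    for start in range(0, n, batch_size):
        batch = images[start : start + batch_size]
        if dynamic:
            batch = np.swapaxes(batch, 0, 1)
        trace = model.infer(batch, collect=False)
        correct += int((trace.prediction == labels[start : start + batch_size]).sum())
    return correct / n
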