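"""Experiment orchestration: seeded train -> attack -> profile -> report.

An experiment config composes the network, training, attack and data
settings plus a seed list.  Each seed trains a model on freshly generated
synthetic scenes, evaluates clean accuracy, adversarial robustness and mean
firing rate, and writes a checkpoint; the summary aggregates mean ± sample
std (ddof=1) across seeds.  The ablation comparison runs the same pipeline
over the 2x2 grid of {attention, learnable} switches with shared data
seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field

import numpy as np

from .adversarial import PGDConfig, robust_accuracy
from .data import make_scene_dataset
from .io import save_checkpoint
from .network import HTDANetwork, NetworkConfig
from .profiler import count_params, estimate_macs, firing_rates
from .trainer import TrainConfig, evaluate_accuracy, train


@dataclass
class DataConfig:
    n_train: int = 1500
    n_test: int = 300
    classes: tuple[int, ...] = (0, 1)
    size: int = 16
    n_channels: int = 1
    seed: int = 0
    label_mode: str = "texture"  # interior-texture labels keep the object informative


@dataclass
class ExperimentConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    attack: PGDConfig = field(default_factory=PGDConfig)
    data: DataConfig = field(default_factory=DataConfig)
    out_dir: str = "runs"
    seeds: tuple[int, ...] = (0, 1, 2)

    def __post_init__(self):
        if not self.seeds:
            raise ValueError("seed list must be non-empty")


def tiny_study_config(attention: bool = True, epochs: int = 15) -> ExperimentConfig:
    """The scaled-down synthetic study conditions (fixed, not a tuning surface).

    Tiny backbone (x=8) on 16x16 grayscale texture-labeled scenes, 2 classes,
    K=4 steps with Tf=2Td, 1500 training / 300 held-out scenes.  Optimizer:
    SGD momentum 0.9, lr 0.01 with a 3-epoch warm-up, batch 100; joint loss
    with alpha=0.5, beta=0.40, gamma=0.51; temperature annealed 1 -> 6 over
    12 epochs.  PGD: eps=32/255, eta=eps/4, 10 iterations.
    """
    from .objectives import LossWeights

    return ExperimentConfig(
        network=NetworkConfig(
            height=16, width=16, in_channels=1, base_channels=8, n_classes=2,
            k_steps=4, td=1.0, tf=2.0, attention=attention, mode="static",
        ),
        training=TrainConfig(
            epochs=epochs, batch_size=100, lr=0.01, warmup_epochs=3,
            loss_weights=LossWeights(alpha=0.5, beta=0.40, gamma=0.51),
        ),
        attack=PGDConfig(epsilon=32 / 255, iterations=10),
        data=DataConfig(n_train=1500, n_test=300, classes=(0, 1), size=16, label_mode="texture"),
        seeds=(0, 1, 2),
    )


_KNOWN_KEYS = {"network", "training", "attack", "data", "out_dir", "seeds"}


def config_from_dict(d: dict) -> ExperimentConfig:
    """Build an ExperimentConfig from a nested plain dict (e.g. parsed YAML)."""
    unknown = set(d) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def build(cls, sub):
        sub = dict(sub or {})
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(sub) - names
        if bad:
            raise ValueError(f"unknown {cls.__name__} keys: {sorted(bad)}")
        for k, v in sub.items():
            if isinstance(v, list):
                sub[k] = tuple(v)
        return cls(**sub)

    from .objectives import LossWeights

    tr = dict(d.get("training") or {})
    if isinstance(tr.get("loss_weights"), dict):
        tr["loss_weights"] = LossWeights(**tr["loss_weights"])
    return ExperimentConfig(
        network=build(NetworkConfig, d.get("network")),
        training=build(TrainConfig, tr),
        attack=build(PGDConfig, d.get("attack")),
        data=build(DataConfig, d.get("data")),
        out_dir=d.get("out_dir", "runs"),
        seeds=tuple(d.get("seeds", (0, 1, 2))),
    )


def _config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class SeedResult:
    seed: int
    train_acc: float
    clean_acc: float
    robust_acc: float
    mean_firing_rate: float
    total_macs: int
    params: int


def run_seed(cfg: ExperimentConfig, seed: int, save_to: str | None = None) -> SeedResult:
    """Train and evaluate one seeded replicate (returns its metric row)."""
    images, labels, _ = make_scene_dataset(
        cfg.data.n_train + cfg.data.n_test,
        classes=cfg.data.classes,
        size=cfg.data.size,
        seed=cfg.data.seed,
        n_channels=cfg.data.n_channels,
        label_mode=cfg.data.label_mode,
    )
    xtr, ytr = images[: cfg.data.n_train], labels[: cfg.data.n_train]
    xte, yte = images[cfg.data.n_train :], labels[cfg.data.n_train :]
    model = HTDANetwork(cfg.network, rng=seed)
    tcfg = dataclasses.replace(cfg.training, seed=seed)
    history = train(model, xtr, ytr, tcfg)
    clean = evaluate_accuracy(model, xte, yte)
    robust = robust_accuracy(model, xte, yte, dataclasses.replace(cfg.attack, seed=seed))
    trace = model.infer(xte[:100], collect=True)
    rates = firing_rates(trace)
    macs = estimate_macs(trace, model)
    if save_to:
        save_checkpoint(model, save_to, extra={"seed": seed, "config_hash": _config_hash(cfg)})
        with open(save_to + ".epochs.tsv", "w") as fh:
            fh.write(f"# seed={seed} config_hash={_config_hash(cfg)}\n")
            fh.write("epoch\tlr\ttemperature\tloss\tloss_c\tloss_m\ttrain_acc\n")
            for h in history:
                fh.write(
                    f"{h.epoch}\t{h.lr:.6f}\t{h.temperature:.3f}\t{h.loss:.6f}"
                    f"\t{h.loss_c:.6f}\t{h.loss_m:.6f}\t{h.train_acc:.4f}\n"
                )
    return SeedResult(
        seed=seed,
        train_acc=history[-1].train_acc,
        clean_acc=clean,
        robust_acc=robust,
        mean_firing_rate=rates.mean_rate,
        total_macs=macs.total,
        params=count_params(model),
    )


def _aggregate(rows: list[SeedResult]) -> dict:
    def ms(vals):
        vals = np.asarray(vals, dtype=np.float64)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    out = {}
    for name in ("train_acc", "clean_acc", "robust_acc", "mean_firing_rate"):
        m, s = ms([getattr(r, name) for r in rows])
        out[name] = {"mean": m, "std": s}
    out["params"] = rows[0].params
    return out


def run_experiment(cfg: ExperimentConfig, dry_run: bool = False) -> dict:
    """The full seeded pipeline; writes checkpoints, a per-seed table and a summary."""
    if dry_run:
        _config_hash(cfg)  # validates serializability
        return {"validated": True, "seeds": list(cfg.seeds)}
    os.makedirs(cfg.out_dir, exist_ok=True)
    chash = _config_hash(cfg)
    rows = []
    t0 = time.time()
    for seed in cfg.seeds:
        ckpt = os.path.join(cfg.out_dir, f"model_seed{seed}.npz")
        rows.append(run_seed(cfg, seed, save_to=ckpt))
    summary = {
        "config_hash": chash,
        "seeds": list(cfg.seeds),
        "per_seed": [dataclasses.asdict(r) for r in rows],
        "aggregate": _aggregate(rows),
        "wall_time_s": time.time() - t0,
    }
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(os.path.join(cfg.out_dir, "per_seed.tsv"), "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        fh.write("seed\ttrain_acc\tclean_acc\trobust_acc\tmean_firing_rate\ttotal_macs\tparams\n")
        for r in rows:
            fh.write(
                f"{r.seed}\t{r.train_acc:.4f}\t{r.clean_acc:.4f}\t{r.robust_acc:.4f}"
                f"\t{r.mean_firing_rate:.5f}\t{r.total_macs}\t{r.params}\n"
            )
    return summary


def compare_ablations(cfg: ExperimentConfig) -> list[dict]:
    """2x2 grid over {attention, learnable}; all cells share the data seeds."""
    table = []
    for attention in (False, True):
        for learnable in (False, True):
            cell_net = dataclasses.replace(cfg.network, attention=attention, learnable=learnable)
            cell = dataclasses.replace(cfg, network=cell_net, out_dir=os.path.join(
                cfg.out_dir, f"att{int(attention)}_learn{int(learnable)}"))
            rows = [run_seed(cell, s) for s in cell.seeds]
            table.append(
                {
                    "attention": attention,
                    "learnable": learnable,
                    "aggregate": _aggregate(rows),
                }
            )
    return table
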