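"""Optimization strategy: cosine-cyclic learning rate with warm restarts,
global gradient-norm clipping, Adam with decoupled weight decay, early
stopping on validation loss, and builders for the ablation variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    EEGSequence,
    FusionModel,
    LabelSequence,
    ModelConfig,
    ValidationError,
    VideoSequence,
    VARIANTS,
)

__all__ = [
    "TrainConfig",
    "AblationSpec",
    "TrainRecord",
    "ArrayDataset",
    "cyclic_lr",
    "clip_gradient",
    "early_stop_check",
    "build_ablation",
    "train",
]


@dataclass
class TrainConfig:
    eta_min: float = 0.0
    eta_max: float = 1e-3
    T_max: Optional[int] = None  # None -> 10 * steps-per-epoch, resolved in train()
    tau: float = 1.0
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    decoupled_weight_decay: bool = True
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if not (0.0 <= self.eta_min < self.eta_max):
            raise ValidationError("need 0 <= eta_min < eta_max")
        if self.tau <= 0:
            raise ValidationError("clip threshold tau must be positive")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.T_max is not None and self.T_max < 1:
            raise ValidationError("T_max must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValidationError("invalid batch_size or max_epochs")


@dataclass
class AblationSpec:
    """Names exactly one model variant to build."""

    variant: str = "full"

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}"
            )


@dataclass
class TrainRecord:
    epochs: list[int] = field(default_factory=list)
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    lr_first_step: list[float] = field(default_factory=list)
    stop_epoch: int = -1
    best_epoch: int = -1
    diverged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_losses,
                "val_loss": self.val_losses,
                "lr_first_step": self.lr_first_step,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class ArrayDataset:
    """Stacked paired sequences: everything the training loop consumes.

    ``labels`` is (N, T); per-sequence training uses ``labels[:, 0]`` (the
    synthetic generator emits constant labels within a sequence).
    """

    eeg: Optional[np.ndarray]  # (N, T, d)
    frames: Optional[np.ndarray]  # (N, T, h, w, c)
    features: Optional[np.ndarray]  # (N, T, h_v)
    labels: np.ndarray  # (N, T)

    def __post_init__(self):
        if (self.frames is None) == (self.features is None):
            raise ValidationError("provide exactly one of frames or features")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValidationError("labels must be (N, T)")

    def __len__(self) -> int:
        return self.labels.shape[0]

    def subset(self, idx) -> "ArrayDataset":
        idx = np.asarray(idx)
        return ArrayDataset(
            None if self.eeg is None else self.eeg[idx],
            None if self.frames is None else self.frames[idx],
            None if self.features is None else self.features[idx],
            self.labels[idx],
        )

    @classmethod
    def from_triples(
        cls, triples: list[tuple[EEGSequence, VideoSequence, LabelSequence]]
    ) -> "ArrayDataset":
        eeg = np.stack([t[0].samples for t in triples])
        if triples[0][1].frames is not None:
            frames = np.stack([t[1].frames for t in triples])
            features = None
        else:
            frames = None
            features = np.stack([t[1].features for t in triples])
        labels = np.stack([t[2].labels for t in triples])
        return cls(eeg, frames, features, labels)


# ---------------------------------------------------------------------------
# Schedule / clipping / stopping primitives
# ---------------------------------------------------------------------------


def cyclic_lr(t_cur: int, cfg: TrainConfig) -> float:
    """Cosine-cyclic learning rate with warm restarts every ``T_max`` steps.

    ``eta = eta_min + (eta_max - eta_min)(1 + cos(pi * (t mod T_max)/T_max))/2``
    """
    if cfg.T_max is None or cfg.T_max < 1:
        raise ValidationError("cyclic_lr needs a resolved T_max >= 1")
    if t_cur < 0:
        raise ValidationError("t_cur must be >= 0")
    tc = t_cur % cfg.T_max
    return cfg.eta_min + 0.5 * (cfg.eta_max - cfg.eta_min) * (
        1.0 + np.cos(np.pi * tc / cfg.T_max)
    )


def clip_gradient(g: np.ndarray, tau: float) -> np.ndarray:
    """``g / max(1, ||g||/tau)``: norm capped at tau, direction preserved."""
    if tau <= 0:
        raise ValidationError("tau must be positive")
    g = np.asarray(g, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValidationError("gradient contains non-finite values")
    norm = float(np.linalg.norm(g))
    return g / max(1.0, norm / tau)


def early_stop_check(
    val_losses: list[float], patience: int
) -> tuple[bool, Optional[int]]:
    """Stop once the running-best validation loss is ``patience`` epochs stale.

    Ties resolve to the earliest epoch. Empty history never stops.
    """
    if patience < 1:
        raise ValidationError("patience must be >= 1")
    if len(val_losses) == 0:
        return False, None
    best = int(np.argmin(val_losses))  # argmin takes the earliest minimum
    return (len(val_losses) - 1 - best) >= patience, best


def build_ablation(
    cfg: ModelConfig, spec: AblationSpec, seed: int = 0
) -> FusionModel:
    """Instantiate the named variant; ``full`` is the unablated assembly."""
    return FusionModel(cfg, seed=seed, variant=spec.variant)


# ---------------------------------------------------------------------------
# The training loop
# ---------------------------------------------------------------------------


def _batch_loss(model: FusionModel, data: ArrayDataset, idx, train: bool):
    eeg = None if data.eeg is None else data.eeg[idx]
    frames = None if data.frames is None else data.frames[idx]
    feats = None if data.features is None else data.features[idx]
    probs = model.forward(eeg, frames, feats, train=train)
    if model.cfg.head_mode == "per_sequence":
        y = data.labels[idx, 0]
    else:
        y = data.labels[idx]
    return model.loss(probs, y)


def evaluate_loss(model: FusionModel, data: ArrayDataset, batch_size: int = 256) -> float:
    """Mean per-sequence loss over ``data`` with dropout off."""
    total, n = 0.0, 0
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        loss = _batch_loss(model, data, idx, train=False)
        total += float(loss.data) * len(idx)
        n += len(idx)
    return total / max(n, 1)


def train(
    model: FusionModel,
    train_data: ArrayDataset,
    val_data: ArrayDataset,
    cfg: TrainConfig,
) -> tuple[FusionModel, TrainRecord]:
    """Adam + decoupled weight decay, cyclic LR, global-norm clipping,
    early stopping; restores the best-validation parameters on exit.
    """
    record = TrainRecord()
    if cfg.max_epochs == 0:
        return model, record

    n = len(train_data)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    sched = cfg if cfg.T_max is not None else _with_tmax(cfg, 10 * steps_per_epoch)

    rng = np.random.default_rng(cfg.seed)
    names = sorted(model.params)
    m = {k: np.zeros_like(model.params[k].data) for k in names}
    v = {k: np.zeros_like(model.params[k].data) for k in names}
    adam_t = 0
    global_step = 0
    best_state = model.state_arrays()
    best_val = np.inf

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        lr_first = None
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            model.zero_grad()
            loss = _batch_loss(model, train_data, idx, train=True)
            if not np.isfinite(loss.data):
                record.diverged = True
                record.stop_epoch = epoch
                model.load_state_arrays(best_state)
                return model, record
            loss.backward()

            grads = [
                model.params[k].grad
                if model.params[k].grad is not None
                else np.zeros_like(model.params[k].data)
                for k in names
            ]
            if not cfg.decoupled_weight_decay:
                # coupled decay flows through the adaptive moments
                grads = [
                    g + cfg.weight_decay * model.params[k].data
                    for k, g in zip(names, grads)
                ]
            flat = np.concatenate([g.ravel() for g in grads])
            flat = clip_gradient(flat, cfg.tau)

            lr = cyclic_lr(global_step, sched)
            if lr_first is None:
                lr_first = lr
            adam_t += 1
            pos = 0
            for k, g in zip(names, grads):
                gc = flat[pos : pos + g.size].reshape(g.shape)
                pos += g.size
                m[k] = cfg.adam_beta1 * m[k] + (1 - cfg.adam_beta1) * gc
                v[k] = cfg.adam_beta2 * v[k] + (1 - cfg.adam_beta2) * gc**2
                mhat = m[k] / (1 - cfg.adam_beta1**adam_t)
                vhat = v[k] / (1 - cfg.adam_beta2**adam_t)
                p = model.params[k]
                step = mhat / (np.sqrt(vhat) + cfg.adam_eps)
                if cfg.decoupled_weight_decay:
                    step = step + cfg.weight_decay * p.data
                p.data -= lr * step
            epoch_loss += float(loss.data) * len(idx)
            global_step += 1

        val_loss = evaluate_loss(model, val_data)
        record.epochs.append(epoch)
        record.train_losses.append(epoch_loss / n)
        record.val_losses.append(val_loss)
        record.lr_first_step.append(float(lr_first))

        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_arrays()
        stop, best_epoch = early_stop_check(record.val_losses, cfg.patience)
        record.best_epoch = int(best_epoch)
        record.stop_epoch = epoch
        if stop:
            break

    model.load_state_arrays(best_state)
    return model, record


def _with_tmax(cfg: TrainConfig, t_max: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, T_max=t_max)
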