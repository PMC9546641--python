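"""Training, evaluation and prediction driver.

Defaults follow the published recipe: adaptive-moment gradient descent at
learning rate 0.001, 3 routing iterations, batches of 16-32 shuffled every
epoch, up to 100 epochs with early stopping after `patience` optimizer steps
without validation improvement, and the best-validation checkpoint kept for
inference. The spread-loss margin ramps linearly from 0.2 to 0.9 over the
first 20% of steps, then stays constant. The total loss is the spread loss
on class activations plus the negative-likelihood loss on the activations
normalized to a simplex.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Adam
from .network import (ArchitectureSpec, VMGCapsNet, build_model, nll_loss,
                      spread_loss)
from .uncertainty import UncertaintyReport, predictive_runs, summarize
from .vbgmm import InvalidInputError

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "predict"]


@dataclass
class TrainConfig:
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    lr: float = 0.001
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10_000           # optimizer steps without val improvement
    seed: int = 0
    margin_lo: float = 0.2
    margin_hi: float = 0.9
    margin_warmup_frac: float = 0.2
    grad_clip: float | None = None      # global-norm gradient clipping
    lr_halve_every: int | None = None   # optional decay: halve every n epochs
    restore_best: bool = True           # return best-val weights (else final)
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise InvalidInputError("lr > 0, epochs >= 1, batch_size >= 1")


@dataclass
class TrainResult:
    model: VMGCapsNet
    history: list = field(default_factory=list)  # per-epoch metric dicts
    best_epoch: int = 0
    best_val_accuracy: float = 0.0
    checkpoint_path: str | None = None
    stopped_early: bool = False

    def history_csv(self) -> str:
        cols = ["epoch", "train_loss", "train_accuracy", "val_loss",
                "val_accuracy", "margin", "lr", "seconds"]
        lines = [",".join(cols)]
        for row in self.history:
            lines.append(",".join(f"{row[c]:.6g}" for c in cols))
        return "\n".join(lines) + "\n"


def _clip_grad_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params
                        if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _batch_loss(model: VMGCapsNet, x: np.ndarray, y: np.ndarray,
                margin: float):
    out = model.forward(x)
    a = out["class_activations"]
    probs = a * (1.0 / ad.tsum(a, axis=1, keepdims=True))
    loss = spread_loss(a, y, margin) + nll_loss(probs, y)
    return loss, a.data


def train(config: TrainConfig, train_images: np.ndarray,
          train_labels: np.ndarray, val_images: np.ndarray | None = None,
          val_labels: np.ndarray | None = None) -> TrainResult:
    """Train a VMG capsule classifier; returns the best-validation model.

    Without a validation split the training set doubles as one (useful for
    tiny smoke runs). Deterministic given ``config.seed`` on one device.
    """
    x = np.asarray(train_images)
    y = np.asarray(train_labels)
    if len(x) != len(y) or len(x) == 0:
        raise InvalidInputError("empty or mismatched training data")
    if val_images is None:
        val_images, val_labels = x, y

    model = build_model(config.arch, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    n_batches = int(np.ceil(len(y) / config.batch_size))
    total_steps = config.epochs * n_batches
    warmup = max(1, int(config.margin_warmup_frac * total_steps))

    best_state: dict | None = None
    best_val = -1.0
    best_epoch = 0
    steps_since_best = 0
    step = 0
    stopped = False
    history = []
    t0 = time.time()
    for epoch in range(config.epochs):
        if config.lr_halve_every and epoch and epoch % config.lr_halve_every == 0:
            opt.lr *= 0.5
        order = rng.permutation(len(y))
        ep_loss = 0.0
        ep_correct = 0
        margin = config.margin_lo
        for b in range(n_batches):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            margin = config.margin_lo + (config.margin_hi - config.margin_lo) \
                * min(1.0, step / warmup)
            opt.zero_grad()
            loss, acts = _batch_loss(model, x[idx], y[idx], margin)
            loss.backward()
            if config.grad_clip is not None:
                _clip_grad_norm(model.parameters(), config.grad_clip)
            opt.step()
            step += 1
            steps_since_best += 1
            ep_loss += loss.item() * len(idx)
            ep_correct += int((np.argmax(acts, axis=1) == y[idx]).sum())
        val_metrics = evaluate(model, val_images, val_labels)
        row = {"epoch": epoch, "train_loss": ep_loss / len(y),
               "train_accuracy": ep_correct / len(y),
               "val_loss": val_metrics["mean_nll"],
               "val_accuracy": val_metrics["accuracy"] / 100.0,
               "margin": margin, "lr": opt.lr,
               "seconds": time.time() - t0}
        history.append(row)
        if row["val_accuracy"] > best_val:
            best_val = row["val_accuracy"]
            best_epoch = epoch
            best_state = model.state_dict()
            steps_since_best = 0
        if steps_since_best >= config.patience:
            stopped = True
            break

    if config.restore_best and best_state is not None:
        model.load_state_dict(best_state)
    ckpt_path = None
    if config.checkpoint_dir is not None:
        out = Path(config.checkpoint_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt_path = str(out / "best_model")
        model.save(ckpt_path, extra={"seed": config.seed,
                                     "config": {k: v for k, v in
                                                asdict(config).items()
                                                if k != "arch"},
                                     "best_epoch": best_epoch,
                                     "best_val_accuracy": best_val})
        (out / "metrics.csv").write_text(
            TrainResult(model, history).history_csv())
    return TrainResult(model=model, history=history, best_epoch=best_epoch,
                       best_val_accuracy=best_val, checkpoint_path=ckpt_path,
                       stopped_early=stopped)


def evaluate(model: VMGCapsNet, images: np.ndarray, labels: np.ndarray,
             batch_size: int = 64) -> dict:
    """Deterministic evaluation: accuracy (%), error rate = 100 - accuracy,
    per-class accuracy, confusion matrix and mean NLL."""
    x = np.asarray(images)
    y = np.asarray(labels)
    C = model.spec.n_classes
    preds = np.empty(len(y), dtype=int)
    nll_sum = 0.0
    for i in range(0, len(y), batch_size):
        probs = model.predict_proba(x[i:i + batch_size])
        preds[i:i + batch_size] = probs.argmax(axis=1)
        pt = np.clip(probs[np.arange(len(probs)), y[i:i + batch_size]],
                     1e-12, None)
        nll_sum += float(-np.log(pt).sum())
    confusion = np.zeros((C, C), dtype=int)
    for t, p in zip(y, preds):
        confusion[t, p] += 1
    with np.errstate(invalid="ignore"):
        per_class = np.where(confusion.sum(axis=1) > 0,
                             np.diag(confusion) / confusion.sum(axis=1), np.nan)
    accuracy = 100.0 * float((preds == y).mean())
    return {"accuracy": accuracy, "error_rate": 100.0 - accuracy,
            "per_class_accuracy": per_class, "confusion": confusion,
            "mean_nll": nll_sum / max(1, len(y)), "n": len(y)}


def predict(model: VMGCapsNet, image: np.ndarray, n_runs: int = 100,
            seed: int = 0, sample: bool = True) -> UncertaintyReport:
    """Uncertainty-aware prediction on one image (see
    :mod:`vmgcaps.uncertainty`)."""
    return summarize(predictive_runs(model, image, n_runs=n_runs, seed=seed,
                                     sample=sample))
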