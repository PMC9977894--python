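"""Training, evaluation metrics, cross-validation and ensembling.

Training follows the comparison protocol: binary cross-entropy on the
segmentation capsule length, Adam at learning rate 1e-3 decayed by 0.9 every
60 epochs, at most 250 epochs.  Evaluation pools pixel confusion counts over
a test set (micro-averaging; per-slice macro-averaging is available) and
reports Dice, IoU, sensitivity and specificity.  Cross-validation splits by
volume, never by slice, so no patient contributes to both train and test of
a fold.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .data_io import augment
from .network import GroupCapsNet, NetworkSpec, SegmentationOutput, \
    build_network


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 0.9
    decay_every: int = 60
    max_epochs: int = 250
    batch_size: int = 8
    seed: int = 0
    threshold: float = 0.5
    augment: bool = True
    noise_variance: float = 0.01
    loss_eps: float = 1e-7

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


# ---------------------------------------------------------------------------
# Loss and metrics
# ---------------------------------------------------------------------------

def bce_loss(lengths: Tensor, masks: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy between capsule lengths and the mask.

    Lengths lie in [0, 1) by the squashing bound; eps keeps the logarithms
    finite at the boundaries.
    """
    y = np.asarray(masks, dtype=lengths.dtype)
    if y.shape != lengths.shape:
        raise ValueError(f"mask shape {y.shape} != prediction shape "
                         f"{lengths.shape}")
    p = lengths
    pos = ad.log(p + eps) * Tensor(y)
    negt = ad.log((1.0 - p) + eps) * Tensor(1.0 - y)
    return -(pos + negt).sum() / float(y.size)


@dataclass
class ConfusionCounts:
    """Pixel-level confusion accumulator."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @classmethod
    def from_masks(cls, predicted: np.ndarray, truth: np.ndarray):
        p = np.asarray(predicted, dtype=bool)
        t = np.asarray(truth, dtype=bool)
        if p.shape != t.shape:
            raise ValueError("prediction and truth shapes differ")
        return cls(tp=int((p & t).sum()), fp=int((p & ~t).sum()),
                   tn=int((~p & ~t).sum()), fn=int((~p & t).sum()))

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    dice: float
    iou: float
    sensitivity: float
    specificity: float

    def as_dict(self):
        return {"dice": self.dice, "iou": self.iou,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Dice = 2TP/(2TP+FN+FP), IoU = TP/(TP+FN+FP), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).

    Degenerate-denominator convention: with an empty ground truth and an
    empty prediction the overlap scores are 1; if exactly one of them is
    empty they are 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:               # empty ground truth
        dice = iou = sens = 1.0 if fp == 0 else 0.0
    else:
        dice = 2 * tp / (2 * tp + fn + fp)
        iou = tp / (tp + fn + fp)
        sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    return Metrics(dice=dice, iou=iou, sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def _stack(samples):
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    msks = np.stack([s.mask for s in samples]).astype(np.float32)
    return imgs, msks


def train_model(model: GroupCapsNet, samples, config: TrainConfig,
                epochs: int | None = None, log=None):
    """Train in place; returns the per-epoch mean BCE history."""
    if not samples:
        raise ValueError("empty training set")
    epochs = min(config.max_epochs, epochs or config.max_epochs)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = []
    idx = np.arange(len(samples))
    for epoch in range(epochs):
        opt.lr = config.learning_rate * (
            config.lr_decay ** (epoch // config.decay_every))
        rng.shuffle(idx)
        losses = []
        for start in range(0, len(idx), config.batch_size):
            chunk = [samples[i] for i in idx[start:start + config.batch_size]]
            if config.augment:
                chunk = [augment(s, rng, config.noise_variance)
                         for s in chunk]
            imgs, msks = _stack(chunk)
            opt.zero_grad()
            lengths = model.forward(imgs)
            loss = bce_loss(lengths, msks, eps=config.loss_eps)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log:
            log(f"epoch {epoch + 1}/{epochs} lr={opt.lr:.2e} "
                f"bce={history[-1]:.4f}")
    return history


def evaluate_model(model: GroupCapsNet, samples, threshold: float = 0.5,
                   batch_size: int = 8, macro: bool = False):
    """Pooled (micro-averaged) metrics over a slice set.

    With ``macro=True`` also returns per-slice metrics.
    """
    if not samples:
        raise ValueError("empty evaluation set")
    pooled = ConfusionCounts()
    per_slice = []
    with ad.no_grad():
        for start in range(0, len(samples), batch_size):
            chunk = samples[start:start + batch_size]
            imgs, msks = _stack(chunk)
            lengths = model.forward(imgs).data
            for i, s in enumerate(chunk):
                counts = ConfusionCounts.from_masks(
                    lengths[i] > threshold, s.mask > 0)
                pooled = pooled + counts
                if macro:
                    per_slice.append(compute_metrics(counts))
    metrics = compute_metrics(pooled)
    if macro:
        return metrics, pooled, per_slice
    return metrics, pooled


def ensemble_predict(models, image, threshold: float = 0.5):
    """Average the per-pixel capsule lengths of several models, then
    threshold."""
    if len(models) < 2:
        raise ValueError("an ensemble needs at least 2 models")
    spec0 = models[0].spec
    for m in models[1:]:
        if m.spec != spec0:
            raise ValueError("ensemble members must share one NetworkSpec")
    lengths = np.mean([m.predict(image, threshold).lengths for m in models],
                      axis=0)
    return SegmentationOutput(lengths=lengths, threshold=threshold)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Volume-level k-fold assignment (slices of one scan stay together)."""

    volume_ids: list
    k: int = 5
    seed: int = 0
    assignment: dict = field(default_factory=dict)

    def __post_init__(self):
        vols = list(dict.fromkeys(self.volume_ids))      # stable unique
        if self.k < 2 or self.k > len(vols):
            raise ValueError(f"cannot make {self.k} folds from "
                             f"{len(vols)} volumes")
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(vols))
        self.assignment = {vols[j]: int(i % self.k)
                           for i, j in enumerate(order)}

    def fold_sizes(self):
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def test_volumes(self, fold):
        return [v for v, f in self.assignment.items() if f == fold]

    def train_volumes(self, fold):
        return [v for v, f in self.assignment.items() if f != fold]


def run_fold(plan: FoldPlan, fold: int, spec: NetworkSpec,
             config: TrainConfig, samples, epochs=None, log=None):
    """Train on the fold's training volumes, evaluate on its test volumes."""
    train_ids = set(plan.train_volumes(fold))
    test_ids = set(plan.test_volumes(fold))
    train = [s for s in samples if s.volume_id in train_ids]
    test = [s for s in samples if s.volume_id in test_ids]
    if not train or not test:
        raise ValueError(f"fold {fold}: empty train or test split")
    model = build_network(spec, seed=config.seed * 1000 + fold)
    history = train_model(model, train, config, epochs=epochs, log=log)
    metrics, counts = evaluate_model(model, test, threshold=config.threshold)
    return {"fold": fold, "model": model, "history": history,
            "metrics": metrics, "counts": counts,
            "n_train": len(train), "n_test": len(test)}


def cross_validate(spec: NetworkSpec, config: TrainConfig, samples,
                   k: int = 5, epochs=None, out_dir=None, log=None):
    """Full k-fold cross-validation; optionally writes per-fold and pooled
    metric CSVs."""
    plan = FoldPlan([s.volume_id for s in samples], k=k, seed=config.seed)
    results = []
    pooled = ConfusionCounts()
    for fold in range(k):
        res = run_fold(plan, fold, spec, config, samples, epochs=epochs,
                       log=log)
        pooled = pooled + res["counts"]
        results.append(res)
    summary = compute_metrics(pooled)
    if out_dir is not None:
        out_dir = Path(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        rows = [{"fold": r["fold"], **r["metrics"].as_dict(),
                 "n_train": r["n_train"], "n_test": r["n_test"]}
                for r in results]
        pd.DataFrame(rows).to_csv(out_dir / "fold_metrics.csv", index=False)
        pd.DataFrame([summary.as_dict()]).to_csv(
            out_dir / "pooled_metrics.csv", index=False)
        for r in results:
            pd.DataFrame({"epoch": np.arange(1, len(r["history"]) + 1),
                          "bce": r["history"]}).to_csv(
                out_dir / f"train_log_fold{r['fold']}.csv", index=False)
    return {"plan": plan, "folds": results, "pooled": summary,
            "pooled_counts": pooled}
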