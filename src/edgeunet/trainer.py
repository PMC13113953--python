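"""Training procedure: Adam, early stopping, LR reduction on plateau,
on-the-fly augmentation and multi-output loss logging.

The monitored quantity is the validation total loss (min mode). The
epoch count is a hard cap; early stopping may fire first. Training for
the boundary-sensitive variants uses the BSO objective with the dilated
boundary band; the plain variants (baseline, edge-only) train with
unweighted BCE + Dice (the boundary band widened to the whole frame and
beta = 1), so the loss ablation is exactly the presence of boundary
weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AugmentConfig, augment
from .edges import boundary_band, downsample_target, edge_target
from .losses import LossWeights, multitask_loss
from .network import EdgeAwareUNet, NetworkOutputs
from .nn import Adam
from .synthetic import SamplePair

__all__ = ["TrainConfig", "TrainingResults", "train", "predict_masks",
           "EarlyStopper", "PlateauScheduler"]

MIN_LR = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 8
    epochs: int = 15
    early_stop_patience: int = 10
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    seed: int = 0
    monitor: str = "val_total"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.early_stop_patience < 1 or self.plateau_patience < 1:
            raise ValueError("patience values must be >= 1")


class EarlyStopper:
    """Stop after ``patience`` consecutive non-improving epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.stale = 0

    def update(self, value: float) -> bool:
        """Record one epoch's monitor value; returns True to stop."""
        if value < self.best:
            self.best = value
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` stale epochs."""

    def __init__(self, lr: float, patience: int, factor: float,
                 min_lr: float = MIN_LR):
        self.lr = lr
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0

    def update(self, value: float) -> float:
        if value < self.best:
            self.best = value
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.stale = 0
        return self.lr


def _batch_targets(masks: np.ndarray, factors: tuple[int, ...],
                   bso: bool) -> dict:
    """Assemble loss targets for one batch of binary masks (B, H, W).

    Boundary heads are supervised on max-pooled boundary bands, edge
    heads on max-pooled morphological-gradient edge maps. For the
    plain (non-BSO) loss the band is the whole frame, which turns the
    boundary Dice into an ordinary Dice loss.
    """
    y = masks[..., None].astype(np.float32)
    if bso:
        mb = np.stack([boundary_band(m) for m in masks])[..., None]
    else:
        mb = np.ones_like(y)
    targets = {"mask": y, "boundary_band": mb.astype(np.float32),
               "boundary": {}, "edge": {}}
    if factors:
        bands = [boundary_band(m) for m in masks]
        edges = [edge_target(m) for m in masks]
        for f in factors:
            targets["boundary"][f] = np.stack(
                [downsample_target(b, f) for b in bands])[..., None].astype(np.float32)
            targets["edge"][f] = np.stack(
                [downsample_target(e, f) for e in edges])[..., None].astype(np.float32)
    return targets


def _outputs_to_preds(out: NetworkOutputs) -> dict:
    return {"seg": out.seg[..., None],
            "boundary": {f: a[..., None] for f, a in out.boundary_aux.items()},
            "edge": {f: a[..., None] for f, a in out.edge_attn.items()}}


def _check_finite(breakdown: dict, epoch: int) -> None:
    for term, val in breakdown.items():
        if not np.isfinite(val):
            raise FloatingPointError(
                f"non-finite loss term '{term}' at epoch {epoch}")


@dataclass
class TrainingResults:
    """Fitted-model results: history, best epoch, and evaluation hooks."""

    model: EdgeAwareUNet
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    stopped_early: bool = False
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def predict(self, samples, threshold: float = 0.5) -> np.ndarray:
        return predict_masks(self.model, samples, threshold=threshold)

    def evaluate(self, samples, threshold: float = 0.5, ci_seed: int = 0):
        from .metrics import evaluate_run
        probs = _predict_probs(self.model, samples)
        truths = [s.mask for s in samples]
        return evaluate_run(truths, list(probs), threshold=threshold,
                            ci_seed=ci_seed)

    def summary(self) -> str:
        cfgv = self.model.config.variant
        last = self.history.iloc[-1]
        lines = [
            f"Edge-aware U-Net training results (variant={cfgv})",
            f"  epochs run      : {len(self.history)}"
            + ("  (stopped early)" if self.stopped_early else ""),
            f"  best epoch      : {self.best_epoch}",
            f"  best val loss   : {self.best_val_loss:.6f}",
            f"  final val Dice  : {last['val_dice']:.4f}",
            f"  final val IoU   : {last['val_iou']:.4f}",
            f"  final lr        : {last['lr']:.2e}",
        ]
        return "\n".join(lines)


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator | None):
    idx = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def _predict_probs(model: EdgeAwareUNet, samples, batch_size: int = 8):
    for sel in _iter_batches(len(samples), batch_size, None):
        batch = np.stack([np.asarray(samples[i].image, np.float32)
                          for i in sel])
        yield from model.forward(batch).seg


def train(
    model: EdgeAwareUNet,
    train_samples: list[SamplePair],
    val_samples: list[SamplePair],
    loss_weights: LossWeights | None = None,
    config: TrainConfig | None = None,
    augment_config: AugmentConfig | None = None,
) -> TrainingResults:
    """Train the model; returns results with best-epoch weights restored."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be non-empty")
    cfg = config or TrainConfig()
    bso = model.config.uses_bso_loss
    weights = loss_weights or LossWeights()
    if not bso:
        weights = LossWeights(beta=1.0, lambda1=weights.lambda1,
                              lambda2=weights.lambda2,
                              epsilon=weights.epsilon,
                              alpha_aux=weights.alpha_aux)
    factors = (4, 8) if model.config.has_attention else ()

    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.lr)
    stopper = EarlyStopper(cfg.early_stop_patience)
    sched = PlateauScheduler(cfg.lr, cfg.plateau_patience, cfg.plateau_factor)

    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = 0
    stopped_early = False
    rows = []

    for epoch in range(1, cfg.epochs + 1):
        # ---- training pass
        sums = {"wbce": 0.0, "bdice": 0.0, "seg_total": 0.0, "aux": 0.0,
                "total": 0.0}
        n_seen = 0
        for sel in _iter_batches(len(train_samples), cfg.batch_size, rng):
            batch = [train_samples[i] for i in sel]
            if augment_config is not None:
                batch = [augment(s, augment_config, aug_rng) for s in batch]
            imgs = np.stack([s.image for s in batch]).astype(np.float32)
            masks = np.stack([s.mask for s in batch])
            targets = _batch_targets(masks, factors, bso)
            x = model._to_tensor(imgs)
            preds = model._forward(x, training=True)
            loss, breakdown = multitask_loss(preds, targets, weights)
            _check_finite(breakdown, epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            w = len(batch)
            n_seen += w
            for k in sums:
                sums[k] += breakdown[k] * w
        train_terms = {f"train_{k}": v / n_seen for k, v in sums.items()}

        # ---- validation pass (no augmentation, inference-mode BN)
        vsums = {"wbce": 0.0, "bdice": 0.0, "seg_total": 0.0, "aux": 0.0,
                 "total": 0.0}
        dices, ious = [], []
        n_val = 0
        for sel in _iter_batches(len(val_samples), cfg.batch_size, None):
            batch = [val_samples[i] for i in sel]
            imgs = np.stack([s.image for s in batch]).astype(np.float32)
            masks = np.stack([s.mask for s in batch])
            targets = _batch_targets(masks, factors, bso)
            out = model.forward(imgs)
            _, breakdown = multitask_loss(_outputs_to_preds(out), targets,
                                          weights)
            _check_finite(breakdown, epoch)
            w = len(batch)
            n_val += w
            for k in vsums:
                vsums[k] += breakdown[k] * w
            from .metrics import dice as _dice, iou as _iou
            for m, p in zip(masks, out.seg):
                pb = (p > 0.5).astype(np.uint8)
                dices.append(_dice(m, pb))
                ious.append(_iou(m, pb))
        val_terms = {f"val_{k}": v / n_val for k, v in vsums.items()}

        rows.append({"epoch": epoch, **train_terms, **val_terms,
                     "val_dice": float(np.mean(dices)),
                     "val_iou": float(np.mean(ious)), "lr": opt.lr})

        monitor = val_terms["val_total"]
        if monitor < best_val:
            best_val = monitor
            best_epoch = epoch
            best_state = model.state_dict()
        opt.lr = sched.update(monitor)
        if stopper.update(monitor):
            stopped_early = True
            break

    model.load_state_dict(best_state)
    history = pd.DataFrame(rows)
    return TrainingResults(model=model, history=history,
                           best_epoch=best_epoch, best_val_loss=float(best_val),
                           stopped_early=stopped_early, loss_weights=weights)


def predict_masks(model: EdgeAwareUNet, samples, threshold: float = 0.5,
                  batch_size: int = 8) -> np.ndarray:
    """Binarized segmentation predictions, input resolution, (N, H, W)."""
    probs = np.stack(list(_predict_probs(model, samples, batch_size)))
    return (probs > threshold).astype(np.uint8)
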