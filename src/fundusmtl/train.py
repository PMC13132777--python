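"""Two-stage training loop and the ablation harness.

Training follows a warm-up-then-finetune schedule: stage 1 freezes the
shared encoder and fits only the decoders/head (20 epochs by default),
stage 2 unfreezes everything for end-to-end optimization (80 epochs by
default).  Optimization uses Adam with weight decay, per-step global-norm
gradient clipping, cosine annealing of the learning rate (optionally with
warm restarts), and early stopping on a validation metric (mean AUC when a
classification head exists, Dice for segmentation-only models).  The best
validation checkpoint is what training returns.

The ablation harness trains structural variants — full multi-task,
no-pretraining, segmentation-only, classification-only — under identical
splits, data order and schedules, so metric differences isolate the
architectural change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .losses import LossWeights, class_weights, dice_loss, total_loss, weighted_bce
from .metrics import classification_report, segmentation_report
from .model import ModelConfig, VesselGuidedNet
from .nn import Adam, clip_grad_norm, cosine_lr, no_grad
from .preprocess import AugmentPolicy, apply_transforms
from .synth import FundusSample

__all__ = ["TrainConfig", "TrainHistory", "ArrayDataset", "train",
           "run_ablation", "aggregate_ablation", "pretext_pretrain",
           "evaluate", "ABLATION_ARMS", "metrics_for_arm"]

logger = logging.getLogger(__name__)

ABLATION_ARMS = ("full", "no_pretrain", "seg_only", "cls_only")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (defaults follow the canonical recipe)."""

    stage1_epochs: int = 20
    stage2_epochs: int = 80
    batch_size: int = 16
    lr_init: float = 1e-4
    lr_min: float = 1e-6
    weight_decay: float = 1e-4
    clip_norm: float = 1.0
    early_stop_patience: int = 15
    early_stop_metric: str = "val_mean_auc"
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    restart_period: int | None = None
    augment: AugmentPolicy | None = None
    use_class_weights: bool = True

    def __post_init__(self):
        if min(self.stage1_epochs, self.stage2_epochs, self.batch_size) < 0:
            raise ValueError("counts must be >= 0")
        if self.lr_min > self.lr_init:
            raise ValueError("lr_min must not exceed lr_init")
        if self.early_stop_metric not in ("val_mean_auc", "val_dice"):
            raise ValueError("early_stop_metric must be val_mean_auc or val_dice")

    @classmethod
    def preset(cls, name: str, **overrides) -> "TrainConfig":
        """Named recipes.

        ``canonical``: two-stage 20 + 80 epochs, plain cosine annealing.
        ``cosine-restarts``: 150 epochs, cosine restarts every 30, 0.4/0.6
        loss weighting.
        ``toy-benchmark``: the desk-scale recipe used on 64 px phantoms
        (short schedule, larger learning rate suited to the small
        from-scratch network).
        """
        presets = {
            "canonical": dict(),
            "cosine-restarts": dict(stage1_epochs=0, stage2_epochs=150,
                                   restart_period=30,
                                   loss_weights=LossWeights.preset(
                                       "cosine-restarts")),
            "toy-benchmark": dict(stage1_epochs=2, stage2_epochs=14,
                                  lr_init=3e-3, lr_min=1e-5,
                                  early_stop_patience=14),
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}; choose from "
                           f"{sorted(presets)}")
        return cls(**{**presets[name], **overrides})


@dataclass
class TrainHistory:
    """Per-epoch records plus the best-checkpoint pointer."""

    records: list = field(default_factory=list)
    best_epoch: int = -1
    best_metric: float = -np.inf

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class ArrayDataset:
    """In-memory dataset: images (N,H,W,3), masks (N,H,W) or None, labels."""

    images: np.ndarray
    masks: np.ndarray | None
    labels: np.ndarray | None
    patient_ids: list | None = None

    @classmethod
    def from_samples(cls, samples: list[FundusSample]) -> "ArrayDataset":
        return cls(images=np.stack([s.image for s in samples]),
                   masks=np.stack([s.vessel_mask for s in samples]),
                   labels=np.stack([s.labels for s in samples]),
                   patient_ids=[s.patient_id for s in samples])

    def __len__(self):
        return len(self.images)

    def subset(self, idx) -> "ArrayDataset":
        return ArrayDataset(
            images=self.images[idx],
            masks=None if self.masks is None else self.masks[idx],
            labels=None if self.labels is None else self.labels[idx],
            patient_ids=(None if self.patient_ids is None
                         else [self.patient_ids[i] for i in idx]))


def _augment_batch(images, masks, labels, policy: AugmentPolicy, seeds):
    out_imgs, out_masks = [], []
    for i in range(len(images)):
        sample = FundusSample(image=images[i],
                              vessel_mask=None if masks is None else masks[i],
                              labels=np.zeros(1, dtype=np.int64)
                              if labels is None else labels[i])
        rng = np.random.default_rng(int(seeds[i]))
        aug = apply_transforms(sample, policy.draw(rng))
        out_imgs.append(aug.image)
        out_masks.append(aug.vessel_mask)
    return (np.stack(out_imgs),
            None if masks is None else np.stack(out_masks))


def _forward_losses(model, images, masks, labels, weights, w_cls):
    out = model(images)
    l_seg = l_cls = None
    if out.seg is not None and masks is not None:
        target = masks[:, None].astype(np.float32)
        l_seg = dice_loss(out.seg, target, eps=weights.eps)
    if out.probs is not None and labels is not None:
        l_cls = weighted_bce(out.probs, labels.astype(np.float32), w_cls)
    if l_seg is not None and l_cls is not None:
        loss = total_loss(l_seg, l_cls, weights)
    else:
        loss = l_seg if l_seg is not None else l_cls
    return loss, l_seg, l_cls, out


def evaluate(model: VesselGuidedNet, dataset: ArrayDataset,
             batch_size: int = 32, threshold: float = 0.5) -> dict:
    """Validation metrics: mean AUC / macro F1 and/or Dice, as applicable."""
    model.eval()
    probs, segs = [], []
    with no_grad():
        for i in range(0, len(dataset), batch_size):
            out = model(dataset.images[i:i + batch_size])
            if out.probs is not None:
                probs.append(out.probs.data)
            if out.seg is not None:
                segs.append(out.seg.data[:, 0])
    result = {}
    if probs and dataset.labels is not None:
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rep = classification_report(np.concatenate(probs), dataset.labels,
                                        threshold)
        result["val_mean_auc"] = rep.classification["mean_auc"]
        result["val_macro_f1"] = rep.classification["macro_f1"]
    if segs and dataset.masks is not None:
        rep = segmentation_report(np.concatenate(segs), dataset.masks,
                                  threshold)
        result["val_dice"] = rep.segmentation["dice"]
        result["val_seg_auc"] = rep.segmentation["auc"]
    return result


def train(model: VesselGuidedNet, train_set: ArrayDataset,
          val_set: ArrayDataset, config: TrainConfig
          ) -> tuple[dict, TrainHistory]:
    """Run the two-stage schedule; returns (best state dict, history).

    The model is left loaded with the best-validation weights.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("datasets must be non-empty")
    rng = np.random.default_rng(config.seed)
    w_cls = None
    if (config.use_class_weights and model.config.include_cls_head
            and train_set.labels is not None):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            w_cls = class_weights(train_set.labels)

    metric_name = config.early_stop_metric
    if not model.config.include_cls_head:
        metric_name = "val_dice"
    params = model.parameters()
    encoder = model.encoder_parameters()
    opt = Adam(params, lr=config.lr_init, weight_decay=config.weight_decay)
    total_epochs = config.stage1_epochs + config.stage2_epochs
    history = TrainHistory()
    best_state = model.state_dict()
    stall = 0
    n = len(train_set)

    for epoch in range(total_epochs):
        stage = 1 if epoch < config.stage1_epochs else 2
        for p in encoder:
            p.requires_grad = stage == 2
        lr = cosine_lr(epoch, total_epochs, config.lr_init, config.lr_min,
                       config.restart_period)
        opt.lr = lr
        model.train()
        order = rng.permutation(n)
        epoch_losses = {"total": [], "seg": [], "cls": []}
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            images = train_set.images[idx]
            masks = None if train_set.masks is None else train_set.masks[idx]
            labels = None if train_set.labels is None else train_set.labels[idx]
            if config.augment is not None:
                seeds = rng.integers(2 ** 31, size=len(idx))
                images, masks = _augment_batch(images, masks, labels,
                                               config.augment, seeds)
            loss, l_seg, l_cls, _ = _forward_losses(
                model, images, masks, labels, config.loss_weights, w_cls)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}: "
                    f"seg={None if l_seg is None else float(l_seg.data)} "
                    f"cls={None if l_cls is None else float(l_cls.data)}")
            model.zero_grad()
            loss.backward()
            clip_grad_norm(params, config.clip_norm)
            opt.step()
            epoch_losses["total"].append(float(loss.data))
            if l_seg is not None:
                epoch_losses["seg"].append(float(l_seg.data))
            if l_cls is not None:
                epoch_losses["cls"].append(float(l_cls.data))

        val = evaluate(model, val_set, batch_size=64)
        metric = val.get(metric_name)
        if metric is None:
            raise RuntimeError(f"early-stop metric {metric_name} unavailable "
                               f"for this model/dataset combination")
        record = {"epoch": epoch, "stage": stage, "lr": lr,
                  "train_loss": float(np.mean(epoch_losses["total"])),
                  "train_loss_seg": (float(np.mean(epoch_losses["seg"]))
                                     if epoch_losses["seg"] else None),
                  "train_loss_cls": (float(np.mean(epoch_losses["cls"]))
                                     if epoch_losses["cls"] else None),
                  **val}
        history.records.append(record)
        logger.info("epoch %d stage %d lr %.2e loss %.4f %s=%.4f", epoch,
                    stage, lr, record["train_loss"], metric_name, metric)
        if metric > history.best_metric:
            history.best_metric = metric
            history.best_epoch = epoch
            best_state = model.state_dict()
            stall = 0
        else:
            stall += 1
            if stall > config.early_stop_patience:
                logger.info("early stop at epoch %d (patience %d)", epoch,
                            config.early_stop_patience)
                break

    for p in encoder:
        p.requires_grad = True
    model.load_state_dict(best_state)
    model.eval()
    return best_state, history


# --------------------------------------------------------------- pretraining
def pretext_pretrain(model_config: ModelConfig, train_set: ArrayDataset,
                     val_set: ArrayDataset, epochs: int = 4,
                     seed: int = 0, lr: float = 3e-3) -> dict:
    """Train a segmentation-only model briefly as an initialization pretext.

    Returns the resulting state dict; callers transplant the encoder weights
    into a fresh model via :func:`load_encoder_weights`.  This realizes a
    "pretrained encoder" initialization contract at desk scale.
    """
    cfg = replace(model_config, include_cls_head=False,
                  include_seg_decoder=True)
    net = VesselGuidedNet(cfg, init_seed=seed)
    tc = TrainConfig(stage1_epochs=0, stage2_epochs=epochs, lr_init=lr,
                     lr_min=lr / 10, early_stop_patience=epochs,
                     early_stop_metric="val_dice", seed=seed,
                     use_class_weights=False)
    state, _ = train(net, train_set, val_set, tc)
    return state


def load_encoder_weights(model: VesselGuidedNet, state: dict):
    """Copy stem/stage weights from ``state`` into ``model`` (names must match)."""
    own = dict(model.named_parameters())
    buffers = {name: (owner, attr) for name, owner, attr
               in model.named_buffers()}
    loaded = 0
    for name, arr in state.items():
        if not name.startswith(("stem", "stages")):
            continue
        arr = np.asarray(arr, dtype=np.float32).copy()
        if name in own:
            own[name].data = arr
            loaded += 1
        elif name in buffers:
            owner, attr = buffers[name]
            setattr(owner, attr, arr)
    if loaded == 0:
        raise ValueError("no encoder weights found in checkpoint state")
    return loaded


# ------------------------------------------------------------------ ablation
def _arm_model_config(base: ModelConfig, arm: str) -> ModelConfig:
    if arm in ("full", "no_pretrain"):
        return base
    if arm == "seg_only":
        return replace(base, include_cls_head=False)
    if arm == "cls_only":
        return replace(base, include_seg_decoder=False, fusion_enabled=False)
    raise ValueError(f"unknown ablation arm {arm!r}")


def metrics_for_arm(arm: str) -> tuple[str, ...]:
    """Which headline metrics an arm defines; mismatches raise."""
    table = {"full": ("dice", "mean_auc", "f1"),
             "no_pretrain": ("dice", "mean_auc", "f1"),
             "seg_only": ("dice",),
             "cls_only": ("mean_auc", "f1")}
    if arm not in table:
        raise ValueError(f"unknown ablation arm {arm!r}")
    return table[arm]


def run_ablation(model_config: ModelConfig, train_config: TrainConfig,
                 train_set: ArrayDataset, val_set: ArrayDataset,
                 eval_set: ArrayDataset, arms=("full", "seg_only", "cls_only"),
                 seeds=(0, 1, 2), pretext_state: dict | None = None
                 ) -> pd.DataFrame:
    """Train every (arm, seed) under identical data and schedule.

    Returns one row per run with the arm's defined metrics measured on
    ``eval_set``.  ``pretext_state`` (encoder weights) initializes every arm
    except ``no_pretrain``; when omitted, all arms start from random
    initialization and ``no_pretrain`` is meaningful only structurally.
    """
    if len(seeds) < 1:
        raise ValueError("at least one seed is required")
    rows = []
    for arm in arms:
        wanted = metrics_for_arm(arm)
        for seed in seeds:
            cfg = _arm_model_config(model_config, arm)
            net = VesselGuidedNet(cfg, init_seed=seed)
            if pretext_state is not None and arm != "no_pretrain":
                load_encoder_weights(net, pretext_state)
            tc = replace(train_config, seed=seed,
                         early_stop_metric=("val_dice" if arm == "seg_only"
                                            else "val_mean_auc"))
            _, history = train(net, train_set, val_set, tc)
            ev = evaluate(net, eval_set)
            row = {"arm": arm, "seed": seed,
                   "best_epoch": history.best_epoch}
            if "dice" in wanted:
                row["dice"] = ev["val_dice"]
            if "mean_auc" in wanted:
                row["mean_auc"] = ev["val_mean_auc"]
            if "f1" in wanted:
                row["f1"] = ev["val_macro_f1"]
            rows.append(row)
            logger.info("ablation %s seed %d -> %s", arm, seed, row)
    return pd.DataFrame(rows)


def aggregate_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd per arm over seeds."""
    metric_cols = [c for c in ("dice", "mean_auc", "f1") if c in table]
    agg = table.groupby("arm")[metric_cols].agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
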