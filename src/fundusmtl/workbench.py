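"""Experiment orchestration: validated YAML configs, reproducible runs,
structured logging, and multi-run comparison tables.

A run directory is self-describing: it contains the config snapshot, the
split assignment, the trained checkpoint, metrics as JSON/CSV, per-class
Grad-CAM heatmaps, and a JSON-lines log.  Re-running the same config with
the same seeds reproduces the deterministic artifacts bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import synth
from .explain import grad_cam, overlay
from .model import ModelConfig, VesselGuidedNet, save_checkpoint
from .preprocess import AugmentPolicy
from .losses import LossWeights
from .split import SplitSpec, grouped_split, stratified_split
from .train import (ArrayDataset, TrainConfig, aggregate_ablation, evaluate,
                    run_ablation, train)

__all__ = ["ExperimentConfig", "ConfigError", "run", "report", "load_config"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when an experiment config fails schema validation."""


class DatasetSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_samples: int = Field(default=256, ge=2)
    image_size: int = Field(default=64, ge=32)
    seed: int = 0
    paired_eyes: bool = False
    label_flip_prob: float = Field(default=0.0, ge=0.0, le=1.0)


class SplitSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 42
    group_by_patient: bool = False
    stratify: bool = True


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stage_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    blocks_per_stage: tuple[int, int, int, int] = (1, 1, 1, 1)
    hidden_dim: int = 256
    dropout_rate: float = Field(default=0.5, ge=0.0, lt=1.0)
    fusion_enabled: bool = True
    mask_stop_gradient: bool = False
    arm: str = "full"

    @field_validator("arm")
    @classmethod
    def _arm(cls, v):
        if v not in ("full", "no_pretrain", "seg_only", "cls_only"):
            raise ValueError(f"unknown arm {v!r}")
        return v


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: str | None = None
    stage1_epochs: int | None = None
    stage2_epochs: int | None = None
    batch_size: int | None = None
    lr_init: float | None = None
    lr_min: float | None = None
    weight_decay: float | None = None
    clip_norm: float | None = None
    early_stop_patience: int | None = None
    restart_period: int | None = None
    lambda_seg: float | None = None
    lambda_cls: float | None = None
    use_class_weights: bool = True
    augment: bool = False

    def build(self, seed: int, include_cls_head: bool) -> TrainConfig:
        base = (TrainConfig.preset(self.preset) if self.preset
                else TrainConfig())
        overrides: dict = {"seed": seed}
        for name in ("stage1_epochs", "stage2_epochs", "batch_size",
                     "lr_init", "lr_min", "weight_decay", "clip_norm",
                     "early_stop_patience", "restart_period"):
            val = getattr(self, name)
            if val is not None:
                overrides[name] = val
        if self.lambda_seg is not None or self.lambda_cls is not None:
            overrides["loss_weights"] = LossWeights(
                lambda_seg=self.lambda_seg if self.lambda_seg is not None else 0.5,
                lambda_cls=self.lambda_cls if self.lambda_cls is not None else 0.5)
        overrides["use_class_weights"] = self.use_class_weights
        overrides["augment"] = AugmentPolicy() if self.augment else None
        overrides["early_stop_metric"] = ("val_mean_auc" if include_cls_head
                                          else "val_dice")
        return dataclasses.replace(base, **overrides)


class AblationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    arms: tuple[str, ...] = ("full", "seg_only", "cls_only")
    seeds: tuple[int, ...] = (0, 1, 2)


class ExplainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_images: int = Field(default=2, ge=0)
    opacity: float = Field(default=0.5, ge=0.0, le=1.0)


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    output_dir: str = "runs/experiment"
    global_seed: int = 0
    dataset: DatasetSection = DatasetSection()
    split: SplitSection = SplitSection()
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    ablation: AblationSection = AblationSection()
    explain: ExplainSection = ExplainSection()

    @property
    def config_hash(self) -> str:
        payload = self.model_dump(exclude={"output_dir"})
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> ExperimentConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return ExperimentConfig(**raw)
    except FileNotFoundError as exc:
        raise ConfigError(str(exc)) from exc
    except Exception as exc:                       # pydantic ValidationError
        raise ConfigError(f"invalid experiment config {path}: {exc}") from exc


class _JsonlLogger:
    def __init__(self, path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self._fh = open(self.path, "a")

    def log(self, event: str, **fields):
        rec = {"t": time.strftime("%Y-%m-%dT%H:%M:%S"), "event": event,
               **fields}
        self._fh.write(json.dumps(rec, default=str) + "\n")
        self._fh.flush()
        logger.info("%s %s", event, fields)

    def close(self):
        self._fh.close()


def _model_config_for(cfg: ExperimentConfig, num_classes: int) -> ModelConfig:
    m = cfg.model
    return ModelConfig(
        input_size=(cfg.dataset.image_size, cfg.dataset.image_size),
        stage_channels=m.stage_channels,
        blocks_per_stage=m.blocks_per_stage, num_classes=num_classes,
        hidden_dim=m.hidden_dim, dropout_rate=m.dropout_rate,
        fusion_enabled=m.fusion_enabled and m.arm not in ("cls_only",),
        mask_stop_gradient=m.mask_stop_gradient,
        include_seg_decoder=m.arm != "cls_only",
        include_cls_head=m.arm != "seg_only")


def simulate(cfg: ExperimentConfig, out_dir=None):
    """Generate the configured synthetic dataset (optionally writing PNGs)."""
    d = cfg.dataset
    return synth.generate_dataset(
        d.n_samples, seed=d.seed, image_size=d.image_size,
        paired_eyes=d.paired_eyes, label_flip_prob=d.label_flip_prob,
        out_dir=out_dir)


def make_split(cfg: ExperimentConfig, samples):
    labels = np.stack([s.labels for s in samples])
    spec = SplitSpec(ratios=cfg.split.ratios, seed=cfg.split.seed,
                     group_key="patient_id" if cfg.split.group_by_patient
                     else None, stratify=cfg.split.stratify)
    if cfg.split.group_by_patient:
        groups = np.array([s.patient_id for s in samples])
        return grouped_split(labels, groups, spec)
    return stratified_split(labels, spec)


def run(config_path) -> str:
    """Execute a full experiment; returns the artifact directory."""
    cfg = load_config(config_path)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLogger(out / "log.jsonl")
    log.log("start", config_hash=cfg.config_hash)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)

    samples, manifest = simulate(cfg)
    manifest.to_csv(out / "manifest.csv", index=False)
    assignment = make_split(cfg, samples)
    assignment.save(out / "split.csv", paths=manifest["path"].tolist())
    log.log("split", sizes=assignment.sizes, hash=assignment.manifest_hash)

    data = ArrayDataset.from_samples(samples)
    train_set = data.subset(assignment.indices("train"))
    val_set = data.subset(assignment.indices("val"))
    test_set = data.subset(assignment.indices("test"))

    num_classes = samples[0].labels.shape[0]
    mc = _model_config_for(cfg, num_classes)
    tc = cfg.train.build(cfg.global_seed, mc.include_cls_head)
    net = VesselGuidedNet(mc, init_seed=cfg.global_seed)
    _, history = train(net, train_set, val_set, tc)
    history.to_frame().to_csv(out / "history.csv", index=False)
    save_checkpoint(net, str(out / "checkpoint.npz"),
                    extra={"config_hash": cfg.config_hash,
                           "best_epoch": history.best_epoch})
    log.log("trained", best_epoch=history.best_epoch,
            best_metric=history.best_metric)

    metrics = {"config_hash": cfg.config_hash,
               "test": evaluate(net, test_set),
               "val": evaluate(net, val_set)}
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    flat = {f"{split}_{k}": v for split, d in metrics.items()
            if isinstance(d, dict) for k, v in d.items()}
    pd.DataFrame([flat]).to_csv(out / "metrics.csv", index=False)
    log.log("evaluated", **flat)

    if mc.include_cls_head and cfg.explain.n_images > 0:
        import imageio.v3 as iio
        cam_dir = out / "cams"
        cam_dir.mkdir(exist_ok=True)
        sidecars = []
        for i in range(min(cfg.explain.n_images, len(test_set))):
            for c in range(num_classes):
                cam = grad_cam(net, test_set.images[i], c)
                blended = overlay(cam, test_set.images[i],
                                  opacity=cfg.explain.opacity)
                name = f"cam_img{i}_class{c}.png"
                iio.imwrite(cam_dir / name,
                            (blended * 255).round().astype(np.uint8))
                sidecars.append({"file": name, "class_index": c,
                                 "prediction": cam.prediction,
                                 "cam_mean": float(cam.cam.mean()),
                                 "cam_max": float(cam.cam.max())})
        with open(cam_dir / "cams.json", "w") as fh:
            json.dump(sidecars, fh, indent=2)
        log.log("explained", n_maps=len(sidecars))

    log.log("done")
    log.close()
    return str(out)


def run_ablation_experiment(config_path) -> str:
    """Train all configured ablation arms under identical conditions."""
    cfg = load_config(config_path)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonlLogger(out / "log.jsonl")
    samples, _ = simulate(cfg)
    assignment = make_split(cfg, samples)
    data = ArrayDataset.from_samples(samples)
    num_classes = samples[0].labels.shape[0]
    mc = _model_config_for(cfg, num_classes)
    tc = cfg.train.build(cfg.global_seed, True)
    table = run_ablation(mc, tc,
                         data.subset(assignment.indices("train")),
                         data.subset(assignment.indices("val")),
                         data.subset(assignment.indices("test")),
                         arms=cfg.ablation.arms, seeds=cfg.ablation.seeds)
    table.to_csv(out / "ablation.csv", index=False)
    aggregate_ablation(table).to_csv(out / "ablation_summary.csv", index=False)
    log.log("ablation", arms=list(cfg.ablation.arms),
            seeds=list(cfg.ablation.seeds))
    log.close()
    return str(out)


def report(artifact_dirs: list) -> pd.DataFrame:
    """Combine run directories into one comparison table (one row per run)."""
    if not artifact_dirs:
        raise ValueError("at least one artifact directory is required")
    rows = []
    for d in artifact_dirs:
        d = Path(d)
        if (d / "ablation.csv").exists():
            tab = pd.read_csv(d / "ablation.csv")
            tab.insert(0, "run", str(d))
            rows.append(tab)
        elif (d / "metrics.csv").exists():
            tab = pd.read_csv(d / "metrics.csv")
            tab.insert(0, "run", str(d))
            tab.insert(1, "arm", "single")
            tab.insert(2, "seed", -1)
            rows.append(tab)
        else:
            raise ValueError(f"{d} contains no metrics artifacts")
    table = pd.concat(rows, ignore_index=True)
    metric_cols = [c for c in table.columns
                   if table[c].dtype.kind == "f"]
    if not metric_cols:
        raise ValueError("no shared numeric metrics across runs")
    agg = table.groupby("arm")[metric_cols].agg(["mean", "std"])
    agg.columns = ["_".join(c) for c in agg.columns]
    agg = agg.reset_index()
    agg.insert(0, "run", "aggregate")
    agg["seed"] = None
    return pd.concat([table, agg], ignore_index=True)
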