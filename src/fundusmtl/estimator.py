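"""Scikit-learn estimator facade over the multi-task network.

:class:`MultiTaskRetinaNet` wraps model construction, the two-stage training
loop and prediction behind the familiar ``fit`` / ``predict`` /
``predict_proba`` interface so the network composes with sklearn pipelines
and model selection.  ``X`` is an (N, H, W, 3) float array of standardized
images; ``y`` an (N, C) binary label matrix; vessel masks are passed as a
fit parameter (they are a second training target, not a feature).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import ModelConfig, VesselGuidedNet
from .nn import no_grad
from .split import SplitSpec, stratified_split
from .train import ArrayDataset, TrainConfig, evaluate as _evaluate, train as _train

__all__ = ["MultiTaskRetinaNet"]


class MultiTaskRetinaNet(BaseEstimator):
    """Joint vessel segmentation + multi-label disease classification.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`; see
    those classes for semantics.  When no validation data is supplied to
    ``fit``, a stratified ``validation_fraction`` of the training data is
    held out for early stopping and checkpoint selection.
    """

    def __init__(self, stage_channels=(8, 16, 32, 64),
                 blocks_per_stage=(1, 1, 1, 1), hidden_dim=256,
                 dropout_rate=0.5, fusion_enabled=True,
                 mask_stop_gradient=False, include_seg_decoder=True,
                 include_cls_head=True, stage1_epochs=2, stage2_epochs=12,
                 batch_size=16, lr_init=3e-3, lr_min=1e-5, weight_decay=1e-4,
                 clip_norm=1.0, early_stop_patience=12,
                 use_class_weights=True, augment=None,
                 validation_fraction=0.15, threshold=0.5, seed=0):
        self.stage_channels = stage_channels
        self.blocks_per_stage = blocks_per_stage
        self.hidden_dim = hidden_dim
        self.dropout_rate = dropout_rate
        self.fusion_enabled = fusion_enabled
        self.mask_stop_gradient = mask_stop_gradient
        self.include_seg_decoder = include_seg_decoder
        self.include_cls_head = include_cls_head
        self.stage1_epochs = stage1_epochs
        self.stage2_epochs = stage2_epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.lr_min = lr_min
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.early_stop_patience = early_stop_patience
        self.use_class_weights = use_class_weights
        self.augment = augment
        self.validation_fraction = validation_fraction
        self.threshold = threshold
        self.seed = seed

    # ------------------------------------------------------------------- fit
    def _model_config(self, input_size, num_classes) -> ModelConfig:
        return ModelConfig(
            input_size=input_size,
            stage_channels=tuple(self.stage_channels),
            blocks_per_stage=tuple(self.blocks_per_stage),
            num_classes=num_classes, hidden_dim=self.hidden_dim,
            dropout_rate=self.dropout_rate,
            fusion_enabled=self.fusion_enabled,
            mask_stop_gradient=self.mask_stop_gradient,
            include_seg_decoder=self.include_seg_decoder,
            include_cls_head=self.include_cls_head)

    def _train_config(self) -> TrainConfig:
        metric = ("val_mean_auc" if self.include_cls_head else "val_dice")
        return TrainConfig(
            stage1_epochs=self.stage1_epochs,
            stage2_epochs=self.stage2_epochs, batch_size=self.batch_size,
            lr_init=self.lr_init, lr_min=self.lr_min,
            weight_decay=self.weight_decay, clip_norm=self.clip_norm,
            early_stop_patience=self.early_stop_patience,
            early_stop_metric=metric, seed=self.seed,
            augment=self.augment, use_class_weights=self.use_class_weights)

    def fit(self, X, y=None, masks=None, X_val=None, y_val=None,
            masks_val=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (N, H, W, 3)")
        if y is None and masks is None:
            raise ValueError("at least one target (y labels or masks) is "
                             "required")
        if self.include_cls_head and y is None:
            raise ValueError("labels y are required when include_cls_head")
        if self.include_seg_decoder and masks is None:
            raise ValueError("masks are required when include_seg_decoder")
        y = None if y is None else np.asarray(y)
        masks = None if masks is None else np.asarray(masks)
        data = ArrayDataset(images=X, masks=masks, labels=y)

        if X_val is None:
            strat = y if y is not None else np.zeros((len(X), 1), dtype=int)
            frac = self.validation_fraction
            assignment = stratified_split(
                strat, SplitSpec(ratios=(1.0 - frac, frac / 2, frac / 2),
                                 seed=self.seed))
            val_idx = np.concatenate([assignment.indices("test"),
                                      assignment.indices("val")])
            train_idx = assignment.indices("train")
            train_set, val_set = data.subset(train_idx), data.subset(val_idx)
        else:
            train_set = data
            val_set = ArrayDataset(
                images=np.asarray(X_val, dtype=np.float32),
                masks=None if masks_val is None else np.asarray(masks_val),
                labels=None if y_val is None else np.asarray(y_val))

        self.n_classes_ = 0 if y is None else y.shape[1]
        cfg = self._model_config(tuple(X.shape[1:3]),
                                 max(self.n_classes_, 1))
        self.model_ = VesselGuidedNet(cfg, init_seed=self.seed)
        _, self.history_ = _train(self.model_, train_set, val_set,
                                  self._train_config())
        return self

    # ------------------------------------------------------------ prediction
    def _batched(self, X, attr, batch_size=32):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=np.float32)
        outs = []
        with no_grad():
            for i in range(0, len(X), batch_size):
                out = self.model_(X[i:i + batch_size])
                outs.append(getattr(out, attr).data)
        return np.concatenate(outs)

    def predict_proba(self, X) -> np.ndarray:
        """(N, C) per-class sigmoid probabilities."""
        if not self.include_cls_head:
            raise RuntimeError("model has no classification head")
        return self._batched(X, "probs")

    def predict(self, X) -> np.ndarray:
        """(N, C) binary label matrix at the configured threshold."""
        return (self.predict_proba(X) >= self.threshold).astype(int)

    def predict_mask(self, X) -> np.ndarray:
        """(N, H, W) vessel probability maps."""
        if not self.include_seg_decoder:
            raise RuntimeError("model has no segmentation decoder")
        return self._batched(X, "seg")[:, 0]

    def score(self, X, y=None, masks=None) -> float:
        """Mean per-class AUC (classification) or mean Dice (segmentation)."""
        data = ArrayDataset(images=np.asarray(X, dtype=np.float32),
                            masks=None if masks is None else np.asarray(masks),
                            labels=None if y is None else np.asarray(y))
        ev = _evaluate(self.model_, data)
        if "val_mean_auc" in ev:
            return float(ev["val_mean_auc"])
        return float(ev["val_dice"])
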