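"""The vessel-guided multi-task network.

A shared residual encoder feeds two branches: a U-Net-style decoder that
predicts a per-pixel vessel probability map ``M_seg``, and a classification
head whose features are *gated* by that map.  The gate is the element-wise
product

    f_vessel = F4 (*) Downsample(M_seg)

where ``F4`` is the deepest encoder feature and ``Downsample`` average-pools
the probability map to F4's spatial grid (keeping the operation
differentiable, so the classification loss can shape the segmentation
decoder unless a stop-gradient is requested).  Global average pooling of
``F4`` and of the gated map are concatenated into the fused feature the
two-layer classification head consumes; per-class sigmoids produce
independent multi-label probabilities.

The architecture is size-configurable: the same code expresses a
few-thousand-parameter toy network for CPU experiments and a
ResNet-50-scale variant (the stage widths/depths of which match the classic
(3, 4, 6, 3)-block residual backbone).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, ConvTranspose2d, Linear, Module,
                 Sequential, Tensor, concat, functional as F)

__all__ = ["ModelConfig", "VesselGuidedNet", "ForwardOutput", "vessel_gate",
           "save_checkpoint", "load_checkpoint"]

ENCODER_STRIDE = 32     # stem (x2) + pool (x2) + three strided stages (x8)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``stage_channels`` are the output widths of the four residual stages
    (strictly increasing); ``fusion_enabled`` switches the vessel gate on;
    ``mask_stop_gradient`` blocks classification-loss gradients from
    reaching the segmentation decoder through the gate.  ``include_*`` flags
    realize the single-task ablation variants structurally (a disabled
    branch has zero parameters).
    """

    input_size: tuple[int, int] = (64, 64)
    stage_channels: tuple[int, int, int, int] = (8, 16, 32, 64)
    blocks_per_stage: tuple[int, int, int, int] = (1, 1, 1, 1)
    num_classes: int = 5
    hidden_dim: int = 256
    dropout_rate: float = 0.5
    init_mode: str = "he_random"
    fusion_enabled: bool = True
    mask_stop_gradient: bool = False
    include_seg_decoder: bool = True
    include_cls_head: bool = True
    conv_bias: bool = True

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.blocks_per_stage) != 4:
            raise ValueError("exactly four residual stages are required")
        if any(a >= b for a, b in zip(self.stage_channels,
                                      self.stage_channels[1:])):
            raise ValueError("stage_channels must be strictly increasing")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.init_mode not in ("he_random", "pretrained_checkpoint"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if not (self.include_seg_decoder or self.include_cls_head):
            raise ValueError("at least one task branch must be present")

    @classmethod
    def preset(cls, name: str, **overrides) -> "ModelConfig":
        presets = {
            "toy": dict(stage_channels=(8, 16, 32, 64),
                        blocks_per_stage=(1, 1, 1, 1), hidden_dim=256),
            "full": dict(input_size=(224, 224),
                         stage_channels=(256, 512, 1024, 2048),
                         blocks_per_stage=(3, 4, 6, 3), hidden_dim=512),
        }
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}")
        return cls(**{**presets[name], **overrides})


@dataclass
class ForwardOutput:
    """All forward-pass tensors a caller may need (training, CAM, probing)."""

    seg: Tensor | None            # (N, 1, H, W) sigmoid probabilities
    probs: Tensor | None          # (N, C) sigmoid probabilities
    logits: Tensor | None         # (N, C) pre-sigmoid
    pyramid: dict                 # {'stem','f1','f2','f3','f4'} tensors
    fused: dict                   # {'f_global','f_vessel_pooled','f_fused'}


class _ResidualBlock(Module):
    """conv-BN-ReLU-conv-BN with an identity (or projected) shortcut."""

    def __init__(self, in_ch, out_ch, stride, bias, rng):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                            bias=bias, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, stride=1, padding=1,
                            bias=bias, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(in_ch, out_ch, 1, stride=stride, bias=bias,
                               rng=rng)
            self.proj_bn = BatchNorm2d(out_ch)

    def forward(self, x):
        identity = x if self.proj is None else self.proj_bn(self.proj(x))
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        return (out + identity).relu()


class _UpBlock(Module):
    """Transposed-conv x2 upsampling + skip concat + two conv-BN-ReLU."""

    def __init__(self, in_ch, skip_ch, bias, rng):
        super().__init__()
        self.up = ConvTranspose2d(in_ch, skip_ch, 2, stride=2, bias=bias,
                                  rng=rng)
        self.conv1 = Conv2d(2 * skip_ch, skip_ch, 3, padding=1, bias=bias,
                            rng=rng)
        self.bn1 = BatchNorm2d(skip_ch)
        self.conv2 = Conv2d(skip_ch, skip_ch, 3, padding=1, bias=bias,
                            rng=rng)
        self.bn2 = BatchNorm2d(skip_ch)

    def forward(self, x, skip):
        up = self.up(x)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(f"skip/upsample shape mismatch: {up.shape} vs "
                             f"{skip.shape}")
        out = concat([up, skip], axis=1)
        return self.bn2(self.conv2(self.bn1(self.conv1(out)).relu())).relu()


def vessel_gate(f4: Tensor, m_seg: Tensor,
                mask_stop_gradient: bool = False) -> Tensor:
    """Gate deep features by the average-pooled vessel probability map."""
    if m_seg.data.min() < -1e-6 or m_seg.data.max() > 1 + 1e-6:
        raise ValueError("M_seg must lie in [0, 1]")
    if mask_stop_gradient:
        m_seg = m_seg.detach()
    factor = m_seg.shape[2] // f4.shape[2]
    if factor > 1:
        m_seg = F.avg_pool2d(m_seg, factor)
    return f4 * m_seg


class VesselGuidedNet(Module):
    """Shared encoder + segmentation decoder + gated classification head."""

    def __init__(self, config: ModelConfig, init_seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(init_seed)
        self._dropout_rng = np.random.default_rng(
            np.random.default_rng(init_seed + 1).integers(2 ** 31))
        bias = config.conv_bias
        ch = config.stage_channels

        self.stem = Conv2d(3, ch[0], 3, stride=2, padding=1, bias=bias,
                           rng=rng)
        self.stem_bn = BatchNorm2d(ch[0])
        self.stages = []
        in_ch = ch[0]
        for s in range(4):
            blocks = []
            for b in range(config.blocks_per_stage[s]):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(_ResidualBlock(in_ch, ch[s], stride, bias, rng))
                in_ch = ch[s]
            self.stages.append(Sequential(*blocks))

        if config.include_seg_decoder:
            self.up1 = _UpBlock(ch[3], ch[2], bias, rng)
            self.up2 = _UpBlock(ch[2], ch[1], bias, rng)
            self.up3 = _UpBlock(ch[1], ch[0], bias, rng)
            self.up4 = _UpBlock(ch[0], ch[0], bias, rng)
            self.seg_head = Conv2d(ch[0], 1, 1, bias=True, rng=rng)

        if config.include_cls_head:
            width = 2 * ch[3] if (config.fusion_enabled
                                  and config.include_seg_decoder) else ch[3]
            self.fc1 = Linear(width, config.hidden_dim, rng=rng)
            self.fc2 = Linear(config.hidden_dim, config.num_classes, rng=rng)

    def encoder_parameters(self):
        """Parameters of the shared encoder (stem + residual stages)."""
        return [p for name, p in self.named_parameters()
                if name.startswith(("stem", "stages"))]

    # ------------------------------------------------------------ components
    def _check_input(self, x: Tensor):
        h, w = x.shape[2], x.shape[3]
        if h % ENCODER_STRIDE or w % ENCODER_STRIDE:
            raise ValueError(
                f"input spatial size {(h, w)} must be divisible by "
                f"{ENCODER_STRIDE} (stem + pooling + three strided stages)")

    def encode(self, x: Tensor) -> dict:
        """Run the shared encoder; returns the stem feature and F1..F4."""
        self._check_input(x)
        stem = self.stem_bn(self.stem(x)).relu()        # stride 2
        out = F.max_pool2d(stem, 2)             # stride 4
        pyramid = {"stem": stem}
        for s, stage in enumerate(self.stages):
            out = stage(out)
            pyramid[f"f{s + 1}"] = out
        return pyramid

    def decode_mask(self, pyramid: dict) -> Tensor:
        if not self.config.include_seg_decoder:
            raise RuntimeError("this model has no segmentation decoder")
        out = self.up1(pyramid["f4"], pyramid["f3"])
        out = self.up2(out, pyramid["f2"])
        out = self.up3(out, pyramid["f1"])
        out = self.up4(out, pyramid["stem"])
        out = F.upsample_bilinear2x(out)
        return self.seg_head(out).sigmoid()

    def classify(self, pyramid: dict, m_seg: Tensor | None):
        if not self.config.include_cls_head:
            raise RuntimeError("this model has no classification head")
        f4 = pyramid["f4"]
        f_global = F.global_avg_pool(f4)
        fused = {"f_global": f_global, "f_vessel_pooled": None}
        if self.config.fusion_enabled and m_seg is not None:
            f_vessel = vessel_gate(f4, m_seg,
                                   self.config.mask_stop_gradient)
            f_vessel_pooled = F.global_avg_pool(f_vessel)
            fused["f_vessel_pooled"] = f_vessel_pooled
            feat = concat([f_global, f_vessel_pooled], axis=1)
        else:
            feat = f_global
        fused["f_fused"] = feat
        hidden = F.dropout(self.fc1(feat).relu(), self.config.dropout_rate,
                           self._dropout_rng, self.training)
        logits = self.fc2(hidden)
        return logits, fused

    # ---------------------------------------------------------------- forward
    def forward(self, x) -> ForwardOutput:
        """One encoder pass feeding both branches.

        ``x`` may be an (N, 3, H, W) tensor/array or an (N, H, W, 3) array.
        """
        x = as_input_tensor(x)
        pyramid = self.encode(x)
        m_seg = (self.decode_mask(pyramid)
                 if self.config.include_seg_decoder else None)
        logits = probs = None
        fused = {}
        if self.config.include_cls_head:
            logits, fused = self.classify(pyramid, m_seg)
            probs = logits.sigmoid()
        return ForwardOutput(seg=m_seg, probs=probs, logits=logits,
                             pyramid=pyramid, fused=fused)


def as_input_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.shape[-1] == 3 and arr.shape[1] != 3:
        arr = arr.transpose(0, 3, 1, 2)
    return Tensor(np.ascontiguousarray(arr))


# ------------------------------------------------------------- checkpointing
def save_checkpoint(model: VesselGuidedNet, path: str,
                    extra: dict | None = None):
    """Serialize weights (.npz) plus a JSON sidecar with the architecture."""
    np.savez(path, **model.state_dict())
    sidecar = {"model_config": dataclasses.asdict(model.config),
               "extra": extra or {}}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_checkpoint(path: str) -> tuple[VesselGuidedNet, dict]:
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    cfg_dict = sidecar["model_config"]
    for key in ("input_size", "stage_channels", "blocks_per_stage"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    model = VesselGuidedNet(config)
    with np.load(path if str(path).endswith(".npz") else str(path)) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, sidecar.get("extra", {})
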