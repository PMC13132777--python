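"""Grad-CAM class activation maps over the deepest encoder feature.

For a target disease c, the gradient of the pre-sigmoid class logit with
respect to the deepest feature map F4 is spatially averaged into channel
importance weights

    alpha_k = mean_{i,j} d logit_c / d F4[k, i, j]

and the activation map is ReLU(sum_k alpha_k * F4[k]).  The raw map (at F4
resolution) is bilinearly upsampled to the input size and min-max normalized
for display; a constant map normalizes to all zeros.  Because the
classification head is gated by the segmentation output, gradients flow
through the vessel gate by default (the gate is part of the forward graph);
this can be disabled to probe the encoder path alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import transform as sktransform

from .model import VesselGuidedNet, as_input_tensor

__all__ = ["ClassActivationMap", "grad_cam", "overlay"]


@dataclass
class ClassActivationMap:
    cam: np.ndarray             # H x W in [0, 1], display-normalized
    raw_cam: np.ndarray         # F4-resolution, >= 0 (post-ReLU)
    class_index: int
    prediction: float           # sigmoid probability for the class


def grad_cam(model: VesselGuidedNet, image: np.ndarray, class_index: int,
             gate_gradients: bool = True) -> ClassActivationMap:
    """Compute the Grad-CAM heatmap of one class for one image.

    ``gate_gradients=False`` detaches the vessel gate during the backward
    pass so the map reflects only the direct encoder contribution.
    """
    if not model.config.include_cls_head:
        raise RuntimeError("model has no classification head to explain")
    c = int(class_index)
    if not 0 <= c < model.config.num_classes:
        raise IndexError(f"class_index {c} out of range "
                         f"[0, {model.config.num_classes})")
    model.eval()
    original = model.config
    if not gate_gradients and not original.mask_stop_gradient:
        model.config = replace(original, mask_stop_gradient=True)
    try:
        x = as_input_tensor(image)
        out = model(x)
        onehot = np.zeros(out.logits.shape, dtype=np.float32)
        onehot[0, c] = 1.0
        model.zero_grad()
        (out.logits * onehot).sum().backward()
        f4 = out.pyramid["f4"]
        grads = f4.grad[0]                       # (C4, h, w)
        alpha = grads.mean(axis=(1, 2))
        raw = np.maximum((alpha[:, None, None] * f4.data[0]).sum(axis=0), 0.0)
    finally:
        model.config = original
    h, w = x.shape[2], x.shape[3]
    cam = sktransform.resize(raw, (h, w), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    span = cam.max() - cam.min()
    cam = (cam - cam.min()) / span if span > 0 else np.zeros_like(cam)
    return ClassActivationMap(cam=cam.astype(np.float32),
                              raw_cam=raw.astype(np.float32),
                              class_index=c,
                              prediction=float(out.probs.data[0, c]))


def overlay(cam: ClassActivationMap, image: np.ndarray,
            opacity: float = 0.5, cmap: str = "jet") -> np.ndarray:
    """Blend a colormapped heatmap over the image; output in [0, 1]."""
    import matplotlib
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    if img.shape[:2] != cam.cam.shape:
        raise ValueError(f"image {img.shape[:2]} and cam {cam.cam.shape} "
                         "shapes are incompatible")
    if not 0.0 <= opacity <= 1.0:
        raise ValueError("opacity must lie in [0, 1]")
    heat = matplotlib.colormaps[cmap](cam.cam)[..., :3].astype(np.float32)
    return np.clip((1.0 - opacity) * img + opacity * heat, 0.0, 1.0)
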