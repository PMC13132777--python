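"""Preprocessing and augmentation for fundus images.

Two preparation paths exist, mirroring common practice for fundus pipelines:

* the classification path consumes the standardized RGB image (resize to the
  network input size with bilinear interpolation, scale 8-bit values to
  [0, 1]);
* a dedicated segmentation-preprocessing mode additionally enhances vessel
  contrast: extract the green channel (where hemoglobin absorption gives
  vessels their best contrast), apply contrast-limited adaptive histogram
  equalization (CLAHE), then gamma correction.

Training-time augmentation draws each primitive independently with
probability ``p_apply``: horizontal/vertical flips, rotation within a degree
limit, multiplicative brightness/contrast jitter, and hue rotation in HSV
space.  Geometric primitives are applied identically to the vessel mask
(re-binarized at 0.5 after interpolation); labels are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import exposure as skexposure
from skimage import transform as sktransform
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import FundusSample

__all__ = ["AugmentPolicy", "EnhanceParams", "standardize", "enhance_vessels",
           "augment", "FundusStandardizer", "VesselContrastEnhancer"]


@dataclass(frozen=True)
class AugmentPolicy:
    """Stochastic augmentation policy; each primitive fires independently."""

    p_apply: float = 0.5
    rotation_limit: float = 15.0        # degrees
    brightness_limit: float = 0.20      # multiplicative fraction
    contrast_limit: float = 0.20
    hue_limit: float = 10.0             # degrees
    hflip: bool = True
    vflip: bool = True

    def __post_init__(self):
        if not 0.0 <= self.p_apply <= 1.0:
            raise ValueError("p_apply must lie in [0, 1]")
        for name in ("rotation_limit", "brightness_limit", "contrast_limit",
                     "hue_limit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def draw(self, rng: np.random.Generator) -> dict:
        """Sample which primitives fire and their magnitudes."""
        fires = {name: bool(rng.random() < self.p_apply)
                 for name in ("hflip", "vflip", "rotate", "brightness",
                              "contrast", "hue")}
        return {
            "hflip": fires["hflip"] and self.hflip,
            "vflip": fires["vflip"] and self.vflip,
            "angle": (float(rng.uniform(-self.rotation_limit,
                                        self.rotation_limit))
                      if fires["rotate"] else 0.0),
            "brightness": (float(rng.uniform(-self.brightness_limit,
                                             self.brightness_limit))
                           if fires["brightness"] else 0.0),
            "contrast": (float(rng.uniform(-self.contrast_limit,
                                           self.contrast_limit))
                         if fires["contrast"] else 0.0),
            "hue": (float(rng.uniform(-self.hue_limit, self.hue_limit))
                    if fires["hue"] else 0.0),
        }


@dataclass(frozen=True)
class EnhanceParams:
    """Vessel-contrast enhancement parameters.

    ``clahe_clip_limit`` is the CLAHE clipping fraction (scikit-image
    convention, in (0, 1]); ``None`` disables the CLAHE step entirely.
    ``clahe_tile_grid`` divides the image into that many contextual tiles.
    """

    clahe_clip_limit: float | None = 0.02
    clahe_tile_grid: tuple[int, int] = (8, 8)
    gamma: float = 1.2

    def __post_init__(self):
        if self.clahe_clip_limit is not None and self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive (or None)")
        if min(self.clahe_tile_grid) < 1:
            raise ValueError("tile grid dims must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


# ------------------------------------------------------------------ pipeline
def standardize(image: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Resize to ``target_size`` (bilinear) and scale into [0, 1] float32.

    8-bit input is divided by 255; float input is assumed to already be on
    [0, 1] and is clipped.  No resampling happens when the size matches.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float32) / 255.0
    else:
        img = np.clip(img.astype(np.float32), 0.0, 1.0)
    if img.shape[:2] != tuple(target_size):
        img = sktransform.resize(img, target_size, order=1, mode="edge",
                                 anti_aliasing=False,
                                 preserve_range=True).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def enhance_vessels(image: np.ndarray, params: EnhanceParams = EnhanceParams()
                    ) -> np.ndarray:
    """Green channel -> CLAHE -> gamma; returns a single-channel [0, 1] map."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float32) / 255.0
    green = np.clip(img[..., 1].astype(np.float64), 0.0, 1.0)
    if params.clahe_clip_limit is not None:
        rows, cols = params.clahe_tile_grid
        kernel = (max(green.shape[0] // rows, 1),
                  max(green.shape[1] // cols, 1))
        green = skexposure.equalize_adapthist(
            green, kernel_size=kernel, clip_limit=params.clahe_clip_limit)
    return np.clip(green ** params.gamma, 0.0, 1.0).astype(np.float32)


# -------------------------------------------------------------- augmentation
def _rotate_pair(image, mask, angle):
    img = sktransform.rotate(image, angle, order=1, mode="constant", cval=0.0,
                             preserve_range=True).astype(np.float32)
    m = None
    if mask is not None:
        m = sktransform.rotate(mask.astype(np.float32), angle, order=1,
                               mode="constant", cval=0.0, preserve_range=True)
        m = (m >= 0.5).astype(np.uint8)
    return img, m


def apply_transforms(sample: FundusSample, draw: dict) -> FundusSample:
    """Apply a drawn augmentation dict to image and mask; labels untouched."""
    img = sample.image.copy()
    mask = None if sample.vessel_mask is None else sample.vessel_mask.copy()
    if draw.get("hflip"):
        img = img[:, ::-1].copy()
        if mask is not None:
            mask = mask[:, ::-1].copy()
    if draw.get("vflip"):
        img = img[::-1].copy()
        if mask is not None:
            mask = mask[::-1].copy()
    if draw.get("angle"):
        img, mask = _rotate_pair(img, mask, draw["angle"])
    if draw.get("brightness"):
        img = img * (1.0 + draw["brightness"])
    if draw.get("contrast"):
        mean = img.mean()
        img = mean + (img - mean) * (1.0 + draw["contrast"])
    if draw.get("hue"):
        hsv = skcolor.rgb2hsv(np.clip(img, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + draw["hue"] / 360.0) % 1.0
        img = skcolor.hsv2rgb(hsv).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return replace_sample(sample, image=img, vessel_mask=mask)


def replace_sample(sample: FundusSample, **kwargs) -> FundusSample:
    out = FundusSample(image=sample.image, vessel_mask=sample.vessel_mask,
                       labels=sample.labels.copy(),
                       patient_id=sample.patient_id, eye=sample.eye,
                       provenance=sample.provenance)
    for key, val in kwargs.items():
        setattr(out, key, val)
    return out


def augment(sample: FundusSample, policy: AugmentPolicy,
            rng_seed: int) -> FundusSample:
    """Stochastically augment one sample (pure function of sample + seed)."""
    rng = np.random.default_rng(rng_seed)
    return apply_transforms(sample, policy.draw(rng))


# ------------------------------------------------------- sklearn transformers
class FundusStandardizer(BaseEstimator, TransformerMixin):
    """Stateless transformer: batch resize + [0, 1] scaling.

    ``X`` is an iterable of H x W x 3 images (or an (N, H, W, 3) array);
    the output is an (N, h, w, 3) float32 array.
    """

    def __init__(self, target_size=(64, 64)):
        self.target_size = target_size

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.stack([standardize(img, tuple(self.target_size))
                         for img in X])


class VesselContrastEnhancer(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the green/CLAHE/gamma enhancement."""

    def __init__(self, clahe_clip_limit=0.02, clahe_tile_grid=(8, 8),
                 gamma=1.2):
        self.clahe_clip_limit = clahe_clip_limit
        self.clahe_tile_grid = clahe_tile_grid
        self.gamma = gamma

    def _params(self) -> EnhanceParams:
        return EnhanceParams(clahe_clip_limit=self.clahe_clip_limit,
                             clahe_tile_grid=tuple(self.clahe_tile_grid),
                             gamma=self.gamma)

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        params = self._params()
        return np.stack([enhance_vessels(img, params) for img in X])
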