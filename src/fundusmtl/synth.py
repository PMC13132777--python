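"""Synthetic fundus phantoms with known vessel masks and causal disease labels.

Real fundus photographs show a circular field of view containing a branching
vascular tree, the optic disc, the macula, and — in disease — focal lesions
(microaneurysms, hard exudates, hemorrhages).  This module emulates exactly
that structure so every downstream stage (preprocessing, the multi-task
network, metrics, splitting, Grad-CAM) can be exercised end-to-end with a
known ground truth:

* vessel trees grow by a seeded recursive random-walk branching process and
  provide pixel-exact segmentation masks;
* lesions are stamped with configurable counts, sizes and placement
  (near vessels, near the macula, or anywhere in the field);
* multi-label disease tags are *deterministic predicates* over the sample's
  generative parameters (lesion counts/areas and measured vessel
  tortuosity), so labels are perfectly identifiable from provenance unless
  label noise is explicitly requested.

The default dataset configuration mimics the statistical shape of public
multi-disease fundus collections: strong class imbalance with rare
categories, more than 23% of samples carrying two or more labels, and
optional left/right eye pairs per synthetic patient (the two eyes share the
vessel-tree seed but resample lesions, creating intra-patient correlation).
Nothing here attempts photorealism — only the statistical and geometric
structure a segmentation/classification pipeline depends on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "VesselTreeParams", "VesselTree", "LesionSpec", "LesionDistribution",
    "Clause", "DiseaseRule", "LabelRule", "FundusSample",
    "generate_vessel_tree", "render_sample", "generate_dataset",
    "default_tree_params", "default_label_rule", "rfmid_like_distribution",
]

LESION_KINDS = ("microaneurysm", "exudate", "hemorrhage")
PLACEMENTS = ("near_vessel", "near_macula", "anywhere")


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class VesselTreeParams:
    """Parameters of the branching random-walk vessel growth process.

    ``tortuosity`` is the standard deviation (radians) of the per-step
    heading perturbation; ``width_decay`` shrinks the stroke width by that
    factor at each branching depth.
    """

    n_trees: int = 4
    branch_prob: float = 0.4
    tortuosity: float = 0.10
    width_root: float = 2.0
    width_decay: float = 0.85
    max_depth: int = 4
    field_radius: int = 28

    def __post_init__(self):
        if self.n_trees < 0 or self.max_depth < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if self.width_root < 1:
            raise ValueError("width_root must be >= 1 pixel")
        if not 0.0 < self.width_decay <= 1.0:
            raise ValueError("width_decay must lie in (0, 1]")
        if self.field_radius < self.width_root:
            raise ValueError("degenerate field: field_radius < width_root")


@dataclass
class VesselTree:
    """Output of the growth process: raster mask, centerlines, tortuosity."""

    mask: np.ndarray                    # H x W uint8 in {0, 1}
    centerlines: list                   # list of (K_i, 2) float arrays (r, c)
    tortuosity_score: float             # mean |heading change| per unit length


@dataclass(frozen=True)
class LesionSpec:
    """Lesion counts, radii (pixels) and placement per lesion kind."""

    n_microaneurysms: int = 0
    n_exudates: int = 0
    n_hemorrhages: int = 0
    microaneurysm_radius: float = 1.0
    exudate_radius: float = 2.0
    hemorrhage_radius: float = 3.0
    placement: dict = field(default_factory=lambda: {
        "microaneurysm": "near_vessel",
        "exudate": "near_macula",
        "hemorrhage": "anywhere",
    })

    def __post_init__(self):
        for kind in ("microaneurysms", "exudates", "hemorrhages"):
            if getattr(self, f"n_{kind}") < 0:
                raise ValueError("lesion counts must be >= 0")
        for kind in LESION_KINDS:
            if getattr(self, f"{kind}_radius") < 1:
                raise ValueError("lesion radii must be >= 1")
        for kind, place in self.placement.items():
            if kind not in LESION_KINDS:
                raise ValueError(f"unknown lesion kind {kind!r}")
            if place not in PLACEMENTS:
                raise ValueError(f"unknown placement {place!r}")


@dataclass(frozen=True)
class Clause:
    """A single threshold predicate over a provenance feature."""

    feature: str
    threshold: float
    op: str = ">="

    def evaluate(self, provenance: dict) -> bool:
        if self.feature not in provenance:
            raise KeyError(f"rule references undefined feature "
                           f"{self.feature!r}; available: "
                           f"{sorted(provenance)}")
        value = provenance[self.feature]
        if self.op == ">=":
            return bool(value >= self.threshold)
        if self.op == "<=":
            return bool(value <= self.threshold)
        raise ValueError(f"unsupported op {self.op!r}")


@dataclass(frozen=True)
class DiseaseRule:
    """A disease fires when ANY of its clauses holds."""

    name: str
    any_of: tuple

    def evaluate(self, provenance: dict) -> bool:
        return any(c.evaluate(provenance) for c in self.any_of)


@dataclass(frozen=True)
class LabelRule:
    """Deterministic mapping from generative provenance to a label vector."""

    diseases: tuple

    @property
    def num_classes(self) -> int:
        return len(self.diseases)

    @property
    def class_names(self) -> list[str]:
        return [d.name for d in self.diseases]

    def apply(self, provenance: dict) -> np.ndarray:
        return np.array([int(d.evaluate(provenance)) for d in self.diseases],
                        dtype=np.int64)


@dataclass
class FundusSample:
    """One phantom: image, exact vessel mask, labels, identity, provenance."""

    image: np.ndarray                   # H x W x 3 float32 in [0, 1]
    vessel_mask: np.ndarray             # H x W uint8 in {0, 1}
    labels: np.ndarray                  # (C,) int64
    patient_id: str = "p0000"
    eye: str = "left"
    provenance: dict = field(default_factory=dict)


# ------------------------------------------------------------- vessel growth
def generate_vessel_tree(params: VesselTreeParams, rng_seed: int,
                         image_size: tuple[int, int] | None = None) -> VesselTree:
    """Grow a seeded branching vessel tree inside the circular fundus field.

    Each tree starts on the field boundary heading inward; segments are
    pixel-step random walks whose heading is perturbed by N(0, tortuosity)
    per step.  At the end of a segment of depth d < max_depth the walk forks
    into two children with probability ``branch_prob`` (otherwise continues
    as one), so with branch_prob = 1 a tree of depth D has exactly
    2**D - 1 segments.  The reported tortuosity score is the mean absolute
    heading change per unit centerline length.
    """
    if image_size is None:
        side = 2 * params.field_radius + 8
        image_size = (side, side)
    h, w = image_size
    if params.field_radius >= min(h, w) / 2:
        raise ValueError(f"field_radius {params.field_radius} does not fit in "
                         f"image {image_size}")
    rng = np.random.default_rng(rng_seed)
    center = np.array([h / 2.0, w / 2.0])
    seg_len = max(4, int(round(0.9 * params.field_radius / max(params.max_depth, 1))))

    centerlines: list[np.ndarray] = []
    widths: list[float] = []
    turn_sum = 0.0
    turn_steps = 0

    def grow(pos, heading, depth):
        nonlocal turn_sum, turn_steps
        if depth > params.max_depth:
            return
        pts = [pos.copy()]
        for _ in range(seg_len):
            d_heading = rng.normal(0.0, params.tortuosity)
            heading = heading + d_heading
            turn_sum += abs(d_heading)
            turn_steps += 1
            pos = pos + np.array([np.sin(heading), np.cos(heading)])
            pts.append(pos.copy())
        centerlines.append(np.asarray(pts))
        widths.append(params.width_root * params.width_decay ** (depth - 1))
        if depth == params.max_depth:
            return
        if rng.random() < params.branch_prob:
            split = rng.uniform(0.3, 0.7)
            grow(pos.copy(), heading + split, depth + 1)
            grow(pos.copy(), heading - split, depth + 1)
        else:
            grow(pos.copy(), heading, depth + 1)

    for k in range(params.n_trees):
        angle = 2.0 * np.pi * (k + rng.uniform(-0.15, 0.15)) / max(params.n_trees, 1)
        start = center + 0.92 * params.field_radius * np.array(
            [np.sin(angle), np.cos(angle)])
        inward = angle + np.pi + rng.uniform(-0.3, 0.3)
        grow(start, inward, 1)

    mask = _rasterize_centerlines(centerlines, widths, (h, w))
    mask &= _disc_mask((h, w), center, params.field_radius)
    score = turn_sum / turn_steps if turn_steps else 0.0
    return VesselTree(mask=mask.astype(np.uint8), centerlines=centerlines,
                      tortuosity_score=float(score))


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[:shape[0], :shape[1]]
    return ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius ** 2


def _rasterize_centerlines(centerlines, widths, shape) -> np.ndarray:
    """Stamp polylines, grouped by stroke width, via binary dilation."""
    out = np.zeros(shape, dtype=bool)
    by_width: dict[int, np.ndarray] = {}
    for pts, width in zip(centerlines, widths):
        r = int(round(max(width / 2.0, 0.0)))
        layer = by_width.setdefault(r, np.zeros(shape, dtype=bool))
        ij = np.round(pts).astype(int)
        keep = ((ij[:, 0] >= 0) & (ij[:, 0] < shape[0])
                & (ij[:, 1] >= 0) & (ij[:, 1] < shape[1]))
        ij = ij[keep]
        layer[ij[:, 0], ij[:, 1]] = True
    for r, layer in by_width.items():
        if r > 0:
            yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
            layer = ndi.binary_dilation(layer, structure=yy ** 2 + xx ** 2 <= r ** 2)
        out |= layer
    return out


# ------------------------------------------------------------------ rendering
def _stamp_disc(img, center, radius, color, alpha=1.0):
    """Alpha-blend a soft-edged disc onto ``img`` in place; return its area."""
    h, w = img.shape[:2]
    r = int(np.ceil(radius)) + 1
    r0, r1 = max(0, int(center[0]) - r), min(h, int(center[0]) + r + 1)
    c0, c1 = max(0, int(center[1]) - r), min(w, int(center[1]) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return 0
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    weight = np.clip(radius + 0.5 - dist, 0.0, 1.0) * alpha
    patch = img[r0:r1, c0:c1]
    patch += weight[..., None] * (np.asarray(color, dtype=np.float32) - patch)
    return int((weight > 0.5).sum())


def render_sample(tree: VesselTree, lesions: LesionSpec, rule: LabelRule,
                  rng_seed: int, patient_id: str = "p0000",
                  eye: str = "left", noise_sigma: float = 0.01) -> FundusSample:
    """Compose a phantom image from tree + lesions and derive its labels.

    Layer order: circular background field, macular darkening, optic disc,
    lesions, vessels on top (so the stored vessel mask is exactly the
    rendered vessel support).  Labels come from ``rule`` applied to the
    sample's provenance and are noise-free.
    """
    h, w = tree.mask.shape
    rng = np.random.default_rng(rng_seed)
    center = np.array([h / 2.0, w / 2.0])
    radius = _fit_radius(tree, (h, w))
    max_radius = max(lesions.microaneurysm_radius, lesions.exudate_radius,
                     lesions.hemorrhage_radius)
    if max_radius >= radius:
        raise ValueError("lesion radius does not fit inside the fundus field")

    img = np.zeros((h, w, 3), dtype=np.float32) + 0.02
    disc = _disc_mask((h, w), center, radius)
    rr, cc = np.mgrid[:h, :w]
    rad2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / radius ** 2
    base = np.array([0.82, 0.46, 0.28], dtype=np.float32)
    base = base + rng.uniform(-0.04, 0.04, size=3).astype(np.float32)
    shade = (1.0 - 0.25 * np.clip(rad2, 0, 1)).astype(np.float32)
    img[disc] = base[None, :] * shade[disc, None]

    side = rng.choice([-1.0, 1.0])
    od_center = center + np.array([rng.uniform(-0.15, 0.15) * radius,
                                   side * 0.55 * radius])
    macula_center = center + np.array([rng.uniform(-0.1, 0.1) * radius,
                                       -side * 0.15 * radius])
    _stamp_disc(img, macula_center, 0.22 * radius, base * 0.72, alpha=0.8)
    _stamp_disc(img, od_center, 0.16 * radius, (0.95, 0.85, 0.55), alpha=0.95)

    areas = {k: 0 for k in LESION_KINDS}
    counts = {"microaneurysm": lesions.n_microaneurysms,
              "exudate": lesions.n_exudates,
              "hemorrhage": lesions.n_hemorrhages}
    radii = {"microaneurysm": lesions.microaneurysm_radius,
             "exudate": lesions.exudate_radius,
             "hemorrhage": lesions.hemorrhage_radius}
    colors = {"microaneurysm": (0.30, 0.04, 0.36),
              "exudate": (0.97, 0.91, 0.55),
              "hemorrhage": (0.22, 0.03, 0.30)}
    lesion_centers = {k: [] for k in LESION_KINDS}
    for kind in LESION_KINDS:
        place = lesions.placement.get(kind, "anywhere")
        for _ in range(counts[kind]):
            pos = _place_lesion(place, rng, tree, center, macula_center, radius)
            areas[kind] += _stamp_disc(img, pos, radii[kind], colors[kind],
                                       alpha=0.95)
            lesion_centers[kind].append(pos)

    vessel_color = np.array([0.45, 0.13, 0.10], dtype=np.float32)
    img[tree.mask.astype(bool)] = vessel_color

    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape).astype(np.float32)
    np.clip(img, 0.0, 1.0, out=img)

    provenance = {
        "n_microaneurysms": lesions.n_microaneurysms,
        "n_exudates": lesions.n_exudates,
        "n_hemorrhages": lesions.n_hemorrhages,
        "area_microaneurysms": areas["microaneurysm"],
        "area_exudates": areas["exudate"],
        "area_hemorrhages": areas["hemorrhage"],
        "tortuosity": tree.tortuosity_score,
        "lesion_centers": {k: [tuple(map(float, p)) for p in v]
                           for k, v in lesion_centers.items()},
        "lesion_radii": radii,
    }
    labels = rule.apply(provenance)
    return FundusSample(image=img, vessel_mask=tree.mask.astype(np.uint8),
                        labels=labels, patient_id=patient_id, eye=eye,
                        provenance=provenance)


def _fit_radius(tree: VesselTree, shape) -> float:
    return min(shape) / 2.0 - 2.0


def _place_lesion(place, rng, tree, center, macula_center, radius):
    if place == "near_vessel" and tree.centerlines:
        pts = np.concatenate(tree.centerlines, axis=0)
        # keep candidates inside the field
        d = np.linalg.norm(pts - center, axis=1)
        pts = pts[d < 0.85 * radius]
        if len(pts):
            p = pts[rng.integers(len(pts))]
            return p + rng.uniform(-2.0, 2.0, size=2)
    if place == "near_macula":
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0, 0.25 * radius)
        return macula_center + r * np.array([np.sin(ang), np.cos(ang)])
    ang = rng.uniform(0, 2 * np.pi)
    r = np.sqrt(rng.uniform(0, 1)) * 0.8 * radius
    return center + r * np.array([np.sin(ang), np.cos(ang)])


# ------------------------------------------------------------ dataset factory
@dataclass(frozen=True)
class LesionDistribution:
    """Disease-driven sampling law for lesion burden and vessel tortuosity.

    Each disease process is a latent Bernoulli that, when active, adds its
    own characteristic lesion burden on top of a sparse background rate:

    * retinopathy (``p_retinopathy``) adds >= 3 microaneurysms plus a few
      hemorrhages;
    * macular edema (``p_macular_edema``) adds >= 2 exudates, escalating to
      >= 5 with probability ``p_severe_given_edema`` (so the severe label
      always co-occurs with the edema label);
    * a rare hemorrhagic process (``p_hemorrhagic``) adds >= 4 hemorrhages
      (also crossing the retinopathy hemorrhage clause — rare samples are
      multi-label);
    * high vessel tortuosity occurs with ``p_high_tortuosity``.

    The resulting count distributions are strongly bimodal around the label
    thresholds of :func:`default_label_rule`, so the tags are identifiable
    from the rendered image, while class imbalance, rare categories and
    label co-occurrence match the shape of public multi-disease fundus
    datasets.
    """

    p_retinopathy: float = 0.40
    p_macular_edema: float = 0.35
    p_severe_given_edema: float = 0.25
    p_hemorrhagic: float = 0.05
    p_high_tortuosity: float = 0.25
    background_rate: float = 0.15
    tortuosity_low: float = 0.10
    tortuosity_high: float = 0.45
    microaneurysm_radius: float = 2.0
    exudate_radius: float = 2.2
    hemorrhage_radius: float = 3.0

    def sample_tortuosity(self, rng: np.random.Generator) -> float:
        if rng.random() < self.p_high_tortuosity:
            return float(rng.uniform(0.9, 1.1) * self.tortuosity_high)
        return float(rng.uniform(0.8, 1.2) * self.tortuosity_low)

    def sample_lesions(self, rng: np.random.Generator) -> LesionSpec:
        ma = int(rng.poisson(self.background_rate))
        ex = int(rng.poisson(self.background_rate))
        hem = int(rng.poisson(self.background_rate))
        if rng.random() < self.p_retinopathy:
            ma += 3 + int(rng.poisson(2.0))
            hem += int(rng.poisson(0.8))
        if rng.random() < self.p_macular_edema:
            ex += 2 + int(rng.poisson(1.5))
            if rng.random() < self.p_severe_given_edema:
                ex += 3 + int(rng.poisson(1.0))
        if rng.random() < self.p_hemorrhagic:
            hem += 4 + int(rng.poisson(1.0))
        return LesionSpec(
            n_microaneurysms=ma, n_exudates=ex, n_hemorrhages=hem,
            microaneurysm_radius=self.microaneurysm_radius,
            exudate_radius=self.exudate_radius,
            hemorrhage_radius=self.hemorrhage_radius,
        )


def default_tree_params(image_size: int = 64) -> VesselTreeParams:
    """Vessel-growth defaults scaled to a square image side."""
    return VesselTreeParams(field_radius=image_size // 2 - 4,
                            width_root=max(2.0, image_size / 32.0))


def default_label_rule() -> LabelRule:
    """Five-disease rule set over lesion counts and vessel tortuosity.

    The tortuosity threshold 0.2 rad/px separates the bimodal tortuosity
    law cleanly; 'severe_exudation' is a higher-threshold companion of
    'macular_edema' (co-occurring labels), and 'hemorrhagic_rare' is a rare
    category.
    """
    return LabelRule(diseases=(
        DiseaseRule("retinopathy", (Clause("n_microaneurysms", 3),
                                    Clause("n_hemorrhages", 2))),
        DiseaseRule("macular_edema", (Clause("n_exudates", 2),)),
        DiseaseRule("tortuous_vessels", (Clause("tortuosity", 0.2),)),
        DiseaseRule("severe_exudation", (Clause("n_exudates", 5),)),
        DiseaseRule("hemorrhagic_rare", (Clause("n_hemorrhages", 4),)),
    ))


def rfmid_like_distribution() -> LesionDistribution:
    """The default multi-disease, imbalanced, multi-label dataset shape."""
    return LesionDistribution()


def _derive_seed(*parts) -> int:
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def generate_dataset(n_samples: int, seed: int, image_size: int = 64,
                     tree_params: VesselTreeParams | None = None,
                     lesions_distribution: LesionDistribution | None = None,
                     rule: LabelRule | None = None,
                     paired_eyes: bool = False,
                     label_flip_prob: float = 0.0,
                     out_dir: str | os.PathLike | None = None,
                     ) -> tuple[list[FundusSample], pd.DataFrame]:
    """Generate a phantom dataset and its manifest.

    With ``paired_eyes`` the dataset consists of left/right pairs per
    synthetic patient: both eyes reuse the patient's vessel-tree seed (and
    tortuosity), the right eye is mirrored, and lesions are resampled per
    eye.  The manifest has columns ``path, patient_id, eye, label_0..``.
    When ``out_dir`` is given, images and masks are written there as 8-bit
    PNGs and paths point at the files.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if paired_eyes and n_samples % 2:
        raise ValueError("paired_eyes requires an even n_samples")
    tree_params = tree_params or default_tree_params(image_size)
    dist = lesions_distribution or rfmid_like_distribution()
    rule = rule or default_label_rule()
    size = (image_size, image_size)

    samples: list[FundusSample] = []
    rows = []
    n_units = n_samples // 2 if paired_eyes else n_samples
    for unit in range(n_units):
        unit_rng = np.random.default_rng(_derive_seed(seed, unit, 0))
        tortuosity = dist.sample_tortuosity(unit_rng)
        tp = replace(tree_params, tortuosity=tortuosity)
        tree_seed = _derive_seed(seed, unit, 1)
        eyes = ("left", "right") if paired_eyes else ("left",)
        for e_idx, eye in enumerate(eyes):
            tree = generate_vessel_tree(tp, tree_seed, size)
            if eye == "right":
                tree = VesselTree(mask=tree.mask[:, ::-1].copy(),
                                  centerlines=[np.stack([p[:, 0],
                                                         size[1] - 1 - p[:, 1]], axis=1)
                                               for p in tree.centerlines],
                                  tortuosity_score=tree.tortuosity_score)
            lesion_rng = np.random.default_rng(_derive_seed(seed, unit, 2 + e_idx))
            lesions = dist.sample_lesions(lesion_rng)
            pid = f"p{unit:05d}"
            sample = render_sample(tree, lesions, rule,
                                   _derive_seed(seed, unit, 4 + e_idx),
                                   patient_id=pid, eye=eye)
            if label_flip_prob > 0:
                flip_rng = np.random.default_rng(_derive_seed(seed, unit, 6 + e_idx))
                flips = flip_rng.random(sample.labels.shape) < label_flip_prob
                sample.labels = np.where(flips, 1 - sample.labels, sample.labels)
            samples.append(sample)

    rule_names = rule.class_names
    for i, s in enumerate(samples):
        path = f"sample_{i:05d}.png"
        if out_dir is not None:
            path = _write_sample(s, out_dir, i)
        rows.append({"path": path, "patient_id": s.patient_id, "eye": s.eye,
                     **{f"label_{j}": int(s.labels[j])
                        for j in range(len(rule_names))}})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return samples, manifest


def _write_sample(sample: FundusSample, out_dir, index: int) -> str:
    import imageio.v3 as iio

    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, f"sample_{index:05d}.png")
    iio.imwrite(path, (sample.image * 255).round().astype(np.uint8))
    iio.imwrite(os.path.join(out_dir, f"sample_{index:05d}_mask.png"),
                (sample.vessel_mask * 255).astype(np.uint8))
    return path


def provenance_features(samples: list[FundusSample]) -> np.ndarray:
    """(N, 4) matrix of the label-determining provenance features."""
    return np.array([[s.provenance["n_microaneurysms"],
                      s.provenance["n_exudates"],
                      s.provenance["n_hemorrhages"],
                      s.provenance["tortuosity"]] for s in samples])
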