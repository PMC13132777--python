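# fundusmtl

Vessel-guided multi-task analysis of fundus photographs: one network that
simultaneously segments retinal vessels and assigns multiple disease labels
per image, with Grad-CAM heatmaps explaining each prediction — packaged with
a synthetic fundus phantom generator so the entire pipeline runs and is
tested end-to-end on a single CPU, without any external imaging data.

**Who it is for.** Researchers and students studying multi-task medical
image analysis: how a pixel-level auxiliary task (vessel segmentation) can
inform an image-level task (multi-label disease classification), how that
coupling is built and trained, and how to verify every mechanism —
gradients included — against independent oracles.

## The model

A shared residual encoder produces a feature pyramid `F1..F4` (strides
4–32). A U-Net-style decoder with transposed-convolution upsampling and
skip connections emits a vessel probability map `M_seg ∈ [0,1]^{H×W}`. The
classification branch is *gated* by that map:

    f_vessel = F4 ⊙ Downsample(M_seg)
    y_c      = σ( FC₂ ReLU( FC₁ [GAP(F4) ‖ GAP(f_vessel)] ) )    c = 1..C

so vessel-adjacent feature responses are amplified before pooling, and —
because the gate is differentiable — the classification loss reaches back
into the segmentation decoder. Training minimizes

    L = λ_seg · Dice(M_seg, G) + λ_cls · BCE_w(y, t),   λ = (0.5, 0.5)

with per-class positive weights `w_c = (N − n_c)/n_c` against label
imbalance, a two-stage schedule (decoder warm-up with frozen encoder, then
end-to-end fine-tuning), Adam, cosine learning-rate annealing, gradient
clipping and early stopping on validation mean AUC. Grad-CAM maps are
computed from the gradients of each class logit with respect to `F4`.

The network, its autograd engine, Adam, batch normalization and Grad-CAM
are implemented in numpy inside the package (`fundusmtl.nn`) and verified
by finite differences; no deep-learning framework is required.

## Worked example

```python
import numpy as np
from fundusmtl.synth import generate_dataset
from fundusmtl.estimator import MultiTaskRetinaNet
from fundusmtl.metrics import segmentation_report

samples, manifest = generate_dataset(320, seed=7)     # 64x64 phantoms
X = np.stack([s.image for s in samples])
y = np.stack([s.labels for s in samples])             # (N, 5) multi-label
masks = np.stack([s.vessel_mask for s in samples])

est = MultiTaskRetinaNet(stage1_epochs=1, stage2_epochs=6, seed=0)
est.fit(X[:256], y[:256], masks=masks[:256])

print("held-out mean AUC:", round(est.score(X[256:], y[256:]), 3))
seg = est.predict_mask(X[256:])
rep = segmentation_report(seg, masks[256:])
print("held-out Dice:   ", round(rep.segmentation["dice"], 3))
probs = est.predict_proba(X[256:])
print("first sample probabilities:", np.round(probs[0], 2))
print("true labels:               ", y[256])
```

prints (7-epoch demo run; the test suite's 24-epoch benchmark reaches
mean AUC ≈ 0.93 and Dice ≈ 0.96):

```
held-out mean AUC: 0.876
held-out Dice:    0.695
first sample probabilities: [0.56 0.06 0.97 0.01 0.15]
true labels:                [1 0 1 0 0]
```

The five phantom disease classes are retinopathy (microaneurysms /
hemorrhages), macular edema (exudates), tortuous vessels, severe
exudation, and a rare hemorrhagic class; every label is a deterministic
predicate over the phantom's generative parameters, so ground truth is
exact. Grad-CAM heatmaps come from `fundusmtl.explain.grad_cam`; the
`fundusmtl` command-line tool (`simulate`, `split`, `train`, `evaluate`,
`explain`, `ablate`, `report`) orchestrates full reproducible experiment
directories from a YAML config.

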