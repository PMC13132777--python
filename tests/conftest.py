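"""Shared fixtures.

The expensive fixtures (the 1,000-phantom benchmark dataset and the nine
trained ablation models) are session-scoped so the end-to-end, ablation and
Grad-CAM tests all reuse the same study conditions: 64 px phantoms from the
default generator configuration, 600 training / 200 validation / 200
held-out samples, a briefly pretext-pretrained encoder (the desk-scale
analogue of a pretrained backbone, shared by all arms), and the two-stage
desk-scale training recipe.
"""

import os
import warnings

# single-threaded BLAS: reproducible float32 reductions and no thread
# oversubscription on small matmuls (set before numpy spins up its pools)
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from fundusmtl import synth
from fundusmtl.model import ModelConfig, VesselGuidedNet
from fundusmtl.train import (ArrayDataset, TrainConfig, evaluate,
                             load_encoder_weights, pretext_pretrain, train)

BENCHMARK_SEED = 11
ARM_SEEDS = (0, 1, 2)
BENCHMARK_EPOCHS = 22          # stage-2 epochs of the shared recipe


@pytest.fixture(scope="session", autouse=True)
def _single_threaded_blas():
    try:
        from threadpoolctl import threadpool_limits
    except ImportError:
        yield
        return
    with threadpool_limits(limits=1):
        yield


@pytest.fixture(scope="session")
def benchmark():
    """1,000 default-configuration phantoms split 600/200/200."""
    samples, manifest = synth.generate_dataset(1000, seed=BENCHMARK_SEED)
    data = ArrayDataset.from_samples(samples)
    return {
        "samples": samples,
        "manifest": manifest,
        "train": data.subset(range(600)),
        "val": data.subset(range(600, 800)),
        "test": data.subset(range(800, 1000)),
    }


def _arm_config(arm: str) -> ModelConfig:
    base = ModelConfig()
    if arm == "seg_only":
        return ModelConfig(include_cls_head=False)
    if arm == "cls_only":
        return ModelConfig(include_seg_decoder=False, fusion_enabled=False)
    return base


@pytest.fixture(scope="session")
def trained_arms(benchmark):
    """Train full / seg_only / cls_only under identical conditions x 3 seeds.

    Returns {(arm, seed): {"net": model, "metrics": held-out metrics}}.
    """
    results = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in ARM_SEEDS:
            pretext = pretext_pretrain(ModelConfig(), benchmark["train"],
                                       benchmark["val"], epochs=3,
                                       seed=seed + 100)
            for arm in ("full", "seg_only", "cls_only"):
                cfg = _arm_config(arm)
                net = VesselGuidedNet(cfg, init_seed=seed)
                load_encoder_weights(net, pretext)
                metric = "val_dice" if arm == "seg_only" else "val_mean_auc"
                tc = TrainConfig.preset("toy-benchmark",
                                        stage2_epochs=BENCHMARK_EPOCHS,
                                        seed=seed, early_stop_metric=metric)
                train(net, benchmark["train"], benchmark["val"], tc)
                metrics = evaluate(net, benchmark["test"])
                results[(arm, seed)] = {"net": net, "metrics": metrics}
    return results
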