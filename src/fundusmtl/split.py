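"""Multi-label stratified and patient-grouped train/test/validation splits.

Multi-label data cannot be stratified with the usual single-label machinery,
so splitting uses iterative stratification: samples are assigned one label at
a time, rarest label first, to the subset whose desired count for that label
is furthest from being met.  Subset sizes are fixed beforehand by
largest-remainder rounding, so e.g. a 70/20/10 split of 3200 samples always
yields exactly 2240/640/320.

Patient-grouped splitting runs the same procedure on groups (a group's label
vector is the element-wise OR of its members) so both eyes of one patient
always land in the same subset, preventing leakage of intra-patient
correlation into the test set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SplitSpec", "SplitAssignment", "stratified_split", "grouped_split",
           "subset_sizes", "leakage_count"]

SUBSETS = ("train", "test", "val")


@dataclass(frozen=True)
class SplitSpec:
    """Ratios (train, test, val), RNG seed, and stratification options."""

    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 42
    group_key: str | None = None
    stratify: bool = True

    def __post_init__(self):
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("ratios must be three positive numbers")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


@dataclass
class SplitAssignment:
    """Per-sample subset labels plus provenance."""

    subset: np.ndarray                 # array of 'train'/'test'/'val'
    spec: SplitSpec
    sizes: dict = field(default_factory=dict)

    def indices(self, name: str) -> np.ndarray:
        if name not in SUBSETS:
            raise KeyError(f"unknown subset {name!r}")
        return np.flatnonzero(self.subset == name)

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256(",".join(self.subset.tolist()).encode()).hexdigest()

    def to_frame(self, paths=None) -> pd.DataFrame:
        n = len(self.subset)
        paths = paths if paths is not None else [str(i) for i in range(n)]
        return pd.DataFrame({"path": paths, "subset": self.subset})

    def save(self, csv_path, paths=None):
        """Persist as CSV plus a JSON provenance sidecar."""
        csv_path = str(csv_path)
        self.to_frame(paths).to_csv(csv_path, index=False)
        prov = {"ratios": list(self.spec.ratios), "seed": self.spec.seed,
                "group_key": self.spec.group_key,
                "stratify": self.spec.stratify,
                "sizes": self.sizes, "hash": self.manifest_hash}
        with open(csv_path + ".json", "w") as fh:
            json.dump(prov, fh, indent=2)


def subset_sizes(n: int, ratios) -> list[int]:
    """Largest-remainder apportionment of ``n`` items into the given ratios."""
    exact = np.asarray(ratios, dtype=np.float64) * n
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    # distribute leftovers by descending fractional part; ties by position
    order = np.argsort(-(exact - base), kind="stable")
    for k in range(short):
        base[order[k]] += 1
    return base.tolist()


def _iterative_stratify(labels: np.ndarray, caps: list[int],
                        rng: np.random.Generator) -> np.ndarray:
    """Sechidis-style iterative stratification with hard subset capacities.

    Returns an integer subset index per sample.
    """
    n, c = labels.shape
    ratios = np.asarray(caps, dtype=np.float64) / n
    desired = ratios[:, None] * labels.sum(axis=0)[None, :]   # (3, C)
    cap = np.asarray(caps, dtype=np.int64).copy()
    assign = np.full(n, -1, dtype=np.int64)
    unassigned = labels.sum(axis=1) > 0
    while unassigned.any():
        remaining_pos = labels[unassigned].sum(axis=0)
        candidates = np.flatnonzero(remaining_pos > 0)
        if candidates.size == 0:
            break
        lab = candidates[np.argmin(remaining_pos[candidates])]
        members = np.flatnonzero(unassigned & (labels[:, lab] > 0))
        members = members[rng.permutation(members.size)]
        for i in members:
            open_subsets = np.flatnonzero(cap > 0)
            score = desired[open_subsets, lab]
            best = open_subsets[score == score.max()]
            if best.size > 1:                        # tie: most room left
                room = cap[best]
                best = best[room == room.max()]
            s = int(best[0] if best.size == 1 else rng.choice(best))
            assign[i] = s
            cap[s] -= 1
            desired[s] -= labels[i]
            unassigned[i] = False
    # label-free samples: fill by remaining capacity, seeded order
    rest = np.flatnonzero(assign < 0)
    rest = rest[rng.permutation(rest.size)]
    for i in rest:
        s = int(np.argmax(cap))
        assign[i] = s
        cap[s] -= 1
    return assign


def stratified_split(label_matrix, spec: SplitSpec = SplitSpec()) -> SplitAssignment:
    """Split N samples into train/test/val preserving label proportions."""
    labels = np.atleast_2d(np.asarray(label_matrix)).astype(np.int64)
    n = labels.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    caps = subset_sizes(n, spec.ratios)
    if min(caps) == 0:
        raise ValueError(f"ratios {spec.ratios} leave an empty subset for N={n}")
    rng = np.random.default_rng(spec.seed)
    if spec.stratify:
        assign = _iterative_stratify(labels, caps, rng)
    else:
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=np.int64)
        bounds = np.cumsum([0] + caps)
        for s in range(3):
            assign[perm[bounds[s]:bounds[s + 1]]] = s
    subset = np.asarray(SUBSETS, dtype=object)[assign]
    sizes = {name: int((subset == name).sum()) for name in SUBSETS}
    return SplitAssignment(subset=subset, spec=spec, sizes=sizes)


def grouped_split(label_matrix, groups, spec: SplitSpec = SplitSpec()) -> SplitAssignment:
    """Stratified split where all samples of a group share one subset."""
    labels = np.atleast_2d(np.asarray(label_matrix)).astype(np.int64)
    groups = np.asarray(groups)
    if groups.size == 0 or groups.shape[0] != labels.shape[0]:
        raise ValueError("groups must be non-empty, one per sample")
    uniq, inverse = np.unique(groups, return_inverse=True)
    g = uniq.size
    group_labels = np.zeros((g, labels.shape[1]), dtype=np.int64)
    np.maximum.at(group_labels, inverse, labels)
    caps = subset_sizes(g, spec.ratios)
    if min(caps) == 0:
        raise ValueError(f"ratios {spec.ratios} leave an empty subset for "
                         f"{g} groups")
    rng = np.random.default_rng(spec.seed)
    if spec.stratify:
        g_assign = _iterative_stratify(group_labels, caps, rng)
    else:
        perm = rng.permutation(g)
        g_assign = np.empty(g, dtype=np.int64)
        bounds = np.cumsum([0] + caps)
        for s in range(3):
            g_assign[perm[bounds[s]:bounds[s + 1]]] = s
    subset = np.asarray(SUBSETS, dtype=object)[g_assign[inverse]]
    sizes = {name: int((subset == name).sum()) for name in SUBSETS}
    return SplitAssignment(subset=subset, spec=spec, sizes=sizes)


def leakage_count(assignment: SplitAssignment, groups) -> int:
    """Number of groups whose members span more than one subset."""
    groups = np.asarray(groups)
    leaks = 0
    for gid in np.unique(groups):
        if np.unique(assignment.subset[groups == gid]).size > 1:
            leaks += 1
    return leaks
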