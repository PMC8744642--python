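"""Subset construction, label scrambling and active-decoy geometry.

Model derivation uses several independently drawn subsets of the parent
active/decoy collection.  Each subset fixes a number of actives and decoys
for training+validation, splits them 80/20 within each class, and leaves
every unselected compound in a test set — which therefore contains only a
small percentage of actives, as in a realistic screening deck.

Label scrambling (Y-scrambling) retags every active as inactive and an
equal number of randomly chosen decoys as active; retraining on scrambled
labels is the standard randomization check that a model is not a chance
correlation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .preprocessing import DescriptorDataset, save_descriptor_table

__all__ = [
    "SplitSpec",
    "SubsetSplit",
    "SplitResult",
    "DistanceSummary",
    "make_subsets",
    "scramble_labels",
    "active_decoy_distance",
    "save_split",
]


@dataclass
class SplitSpec:
    """How to carve training/validation/test parts out of a parent dataset.

    ``n_active_trainval`` actives and ``n_decoy_trainval`` decoys are drawn
    without replacement for each subset; within each class the draw is split
    ``train_fraction`` / (1 - ``train_fraction``), and everything not drawn
    becomes the subset's test set.
    """

    n_active_trainval: int
    n_decoy_trainval: int
    n_subsets: int = 4
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.n_active_trainval < 2 or self.n_decoy_trainval < 2:
            raise ValueError(
                "need at least 2 actives and 2 decoys per subset to split "
                "into train and validation"
            )


@dataclass
class SubsetSplit:
    index: int
    train: DescriptorDataset
    validation: DescriptorDataset
    test: DescriptorDataset


@dataclass
class SplitResult:
    subsets: list[SubsetSplit]
    spec: SplitSpec


def _train_count(n: int, fraction: float) -> int:
    """Per-class training size: floor(fraction*n) + 1, validation gets the rest.

    The +1 resolves both the exact-multiple case (e.g. 0.8 * 4165 = 3332
    exactly, training takes 3333) and the fractional case in favour of the
    training set, while always leaving at least one validation compound.
    """
    c = math.floor(fraction * n + 1e-9) + 1
    return min(c, n - 1)


def make_subsets(ds: DescriptorDataset, spec: SplitSpec) -> SplitResult:
    """Draw ``spec.n_subsets`` independent train/validation/test partitions.

    Each subset samples ``n_active_trainval + n_decoy_trainval`` compounds
    without replacement from the full parent (subsets may overlap with each
    other), splits them per class by ``train_fraction``, and assigns all
    remaining compounds to the test set.  Fully reproducible from
    ``spec.seed``.
    """
    act_idx = np.flatnonzero(ds.labels)
    dec_idx = np.flatnonzero(~ds.labels)
    if spec.n_active_trainval > act_idx.size:
        raise ValueError(
            f"requested {spec.n_active_trainval} actives but only "
            f"{act_idx.size} available"
        )
    if spec.n_decoy_trainval > dec_idx.size:
        raise ValueError(
            f"requested {spec.n_decoy_trainval} decoys but only "
            f"{dec_idx.size} available"
        )
    rng = np.random.default_rng(spec.seed)
    subsets: list[SubsetSplit] = []
    for s in range(spec.n_subsets):
        sel_a = rng.permutation(act_idx)[: spec.n_active_trainval]
        sel_d = rng.permutation(dec_idx)[: spec.n_decoy_trainval]
        ta = _train_count(spec.n_active_trainval, spec.train_fraction)
        td = _train_count(spec.n_decoy_trainval, spec.train_fraction)
        train_rows = np.sort(np.concatenate([sel_a[:ta], sel_d[:td]]))
        val_rows = np.sort(np.concatenate([sel_a[ta:], sel_d[td:]]))
        used = set(train_rows.tolist()) | set(val_rows.tolist())
        test_rows = np.array(
            [i for i in range(ds.n_compounds) if i not in used], dtype=int
        )
        subsets.append(
            SubsetSplit(
                index=s,
                train=ds.subset_rows(train_rows),
                validation=ds.subset_rows(val_rows),
                test=ds.subset_rows(test_rows),
            )
        )
    return SplitResult(subsets=subsets, spec=spec)


def save_split(result: SplitResult, out_dir: str | Path) -> None:
    """Write one descriptor table per part plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": result.spec.seed,
        "train_fraction": result.spec.train_fraction,
        "n_active_trainval": result.spec.n_active_trainval,
        "n_decoy_trainval": result.spec.n_decoy_trainval,
        "subsets": [],
    }
    for sub in result.subsets:
        entry = {"index": sub.index, "parts": {}}
        for part_name in ("train", "validation", "test"):
            part: DescriptorDataset = getattr(sub, part_name)
            fname = f"subset{sub.index}_{part_name}.csv"
            save_descriptor_table(part, out / fname)
            entry["parts"][part_name] = {
                "file": fname,
                "n_active": part.n_active,
                "n_inactive": part.n_inactive,
            }
        manifest["subsets"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def scramble_labels(ds: DescriptorDataset, seed: int) -> DescriptorDataset:
    """Y-scramble activity labels.

    Every originally active compound becomes inactive and exactly the same
    number of originally inactive compounds, chosen uniformly at random,
    become active.  Descriptor values are untouched, so by construction the
    new 'actives' carry no real signal.
    """
    L = ds.n_active
    O = ds.n_inactive
    if L < 1:
        raise ValueError("dataset has no active compounds to scramble")
    if O < L:
        raise ValueError(
            f"cannot scramble: {O} inactives available but {L} needed as new actives"
        )
    rng = np.random.default_rng(seed)
    dec_idx = np.flatnonzero(~ds.labels)
    new_actives = rng.permutation(dec_idx)[:L]
    labels = np.zeros(ds.n_compounds, dtype=bool)
    labels[new_actives] = True
    return ds.with_labels(labels)


@dataclass
class DistanceSummary:
    """Mean +/- standard deviation of all active-decoy Euclidean distances."""

    mean: float
    std: float
    n_pairs: int


def active_decoy_distance(
    ds: DescriptorDataset, via_pca: bool = False
) -> DistanceSummary:
    """Euclidean distances between every active-decoy pair.

    Distances are computed directly in the (normalized) descriptor space.
    A full-rank principal-component rotation is an isometry, so this equals
    the distance computed over all principal components; ``via_pca=True``
    runs the explicit PCA route for parity checking.
    """
    if ds.n_active < 1 or ds.n_inactive < 1:
        raise ValueError("need at least one active and one decoy")
    X = ds.values
    if via_pca:
        from sklearn.decomposition import PCA

        n_comp = min(X.shape)
        X = PCA(n_components=n_comp).fit_transform(X)
    d = cdist(X[ds.labels], X[~ds.labels])
    return DistanceSummary(
        mean=float(d.mean()), std=float(d.std()), n_pairs=int(d.size)
    )
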