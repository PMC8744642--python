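"""Synthetic active/decoy benchmark with planted, controllable signal.

Emulates the shape of a DUD-E-style screening dataset — a small active
class and a large decoy class described by a few hundred continuous
descriptors — without any real chemistry.  Decoys are drawn from a
standard normal on every informative and noise column; actives are the
same distribution shifted by ``effect_size`` (in SD units) along each
informative column, in the direction of its planted weight.  Redundant
columns are near-copies of earlier columns (parent + small Gaussian
noise) and constant columns carry a single value, so the preprocessing
filters have something real to remove.

Because both classes are Gaussian with equal covariance, the optimal
linear ranker is known in closed form: with k informative columns at
equal unit weights, the planted scorer's expected AUC is
``Phi(effect_size * sqrt(k / 2))``.  That makes the generator an analytic
oracle for the model-derivation and metrics machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .preprocessing import DescriptorDataset

__all__ = ["BenchmarkParams", "GroundTruth", "generate_benchmark", "planted_auc"]


@dataclass
class BenchmarkParams:
    """Shape and signal of one synthetic benchmark draw.

    The descriptor block is laid out deterministically from the counts —
    informative columns first, then pure-noise columns, then redundant
    copies, then constants — so two draws with the same counts share a
    schema and differ only in the sampled values.
    """

    n_active: int = 50
    n_decoy: int = 500
    n_descriptors: int = 100
    n_informative: int = 5
    effect_size: float = 2.0
    n_redundant: int = 10
    n_constant: int = 5
    redundant_noise_sd: float = 0.1
    informative_weights: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_decoy < 1:
            raise ValueError("need at least one active and one decoy")
        if self.n_informative < 0 or self.n_redundant < 0 or self.n_constant < 0:
            raise ValueError("column counts must be non-negative")
        if self.n_informative + self.n_redundant + self.n_constant > self.n_descriptors:
            raise ValueError(
                "n_informative + n_redundant + n_constant must not exceed "
                "n_descriptors"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.redundant_noise_sd <= 0:
            raise ValueError("redundant_noise_sd must be > 0")
        if self.informative_weights is not None:
            w = np.asarray(self.informative_weights, dtype=float)
            if w.shape != (self.n_informative,):
                raise ValueError("informative_weights must have n_informative entries")
            if (w == 0).any():
                raise ValueError("planted weights must be nonzero")
            self.informative_weights = w

    @property
    def n_noise(self) -> int:
        return (
            self.n_descriptors
            - self.n_informative
            - self.n_redundant
            - self.n_constant
        )


@dataclass
class GroundTruth:
    """What was planted: informative columns, weights, nuisance structure."""

    informative: list[str]
    weights: np.ndarray
    redundant_parent: dict[str, str]
    constant: list[str]
    effect_size: float

    def save(self, path: str | Path) -> None:
        payload = {
            "informative": self.informative,
            "weights": np.asarray(self.weights, dtype=float).tolist(),
            "redundant_parent": self.redundant_parent,
            "constant": self.constant,
            "effect_size": self.effect_size,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def planted_auc(effect_size: float, n_informative: int) -> float:
    """Closed-form expected AUC of the planted equal-weight scorer."""
    from scipy.stats import norm

    return float(norm.cdf(effect_size * np.sqrt(n_informative / 2.0)))


def generate_benchmark(p: BenchmarkParams) -> tuple[DescriptorDataset, GroundTruth]:
    """Draw one benchmark dataset; byte-identical for identical parameters."""
    rng = np.random.default_rng(p.seed)
    n = p.n_active + p.n_decoy
    k = p.n_informative
    n_rand = k + p.n_noise  # columns that carry fresh Gaussian draws
    if p.n_redundant > 0 and n_rand == 0:
        raise ValueError("redundant columns need at least one random parent column")

    w = (
        np.ones(k)
        if p.informative_weights is None
        else np.asarray(p.informative_weights, dtype=float)
    )
    base = rng.standard_normal((n, n_rand))
    if k:
        base[: p.n_active, :k] += p.effect_size * np.sign(w)

    blocks = [base]
    redundant_parent: dict[int, int] = {}
    if p.n_redundant:
        red = np.empty((n, p.n_redundant))
        for i in range(p.n_redundant):
            parent = i % n_rand
            redundant_parent[n_rand + i] = parent
            red[:, i] = base[:, parent] + rng.normal(0.0, p.redundant_noise_sd, size=n)
        blocks.append(red)
    if p.n_constant:
        blocks.append(np.ones((n, p.n_constant)))
    values = np.hstack(blocks)

    names = [f"D{j:03d}" for j in range(p.n_descriptors)]
    ids = [f"act_{i:05d}" for i in range(p.n_active)] + [
        f"dec_{i:05d}" for i in range(p.n_decoy)
    ]
    labels = np.zeros(n, dtype=bool)
    labels[: p.n_active] = True

    ds = DescriptorDataset(
        compound_ids=ids, labels=labels, descriptor_names=names, values=values
    )
    gt = GroundTruth(
        informative=names[:k],
        weights=w.copy(),
        redundant_parent={names[c]: names[par] for c, par in redundant_parent.items()},
        constant=names[n_rand + p.n_redundant :],
        effect_size=p.effect_size,
    )
    return ds, gt
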