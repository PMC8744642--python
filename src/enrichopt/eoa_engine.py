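"""Enrichment Optimization Algorithm: MC/SA search for linear ranking models.

The model is a multiple-linear-regression style scoring rule
``score(x) = sum_i w_i x_i`` over a fixed-size subset of (z-scored)
descriptors, used only to *order* compounds — an intercept cannot change an
ordering and is therefore omitted.  Given L actives and O inactives, the
objective for a candidate model is

* primary score  — the number of actives ranked within the first L places;
* secondary score — a tie-breaker in (0, 1] that rewards keeping misplaced
  compounds close to position L.  With displacement
  ``D = sum_{active at rank r > L} (r - L) + sum_{inactive at rank r <= L} (L + 1 - r)``
  the secondary score is ``2 / (1 + exp(D / tau))``: exactly 1 when D = 0
  (perfect separation) and strictly decreasing in D.

The total objective is ``primary + secondary``.  Because the secondary term
never reaches 1 unless separation is perfect, a solution that places one
more active in the top L always beats any rearrangement that does not —
the search optimizes early recognition first, positional tidiness second.

The search itself is Metropolis Monte Carlo over (descriptor subset,
weights) under a saw-tooth simulated-annealing schedule: the temperature-like
term RT is swept linearly downward, then reset, for as many cycles as the
step budget allows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocessing import DescriptorDataset

__all__ = [
    "EoaModel",
    "RankedList",
    "ObjectiveValue",
    "AnnealingSchedule",
    "MoveConfig",
    "OptimizerTrace",
    "rank_compounds",
    "primary_score",
    "secondary_score",
    "objective_value",
    "propose_move",
    "optimize",
]

_FORMAT_VERSION = "1"


@dataclass
class EoaModel:
    """A fixed-size descriptor subset with real weights defining a ranking."""

    descriptor_names: list[str]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.descriptor_names) < 1:
            raise ValueError("model needs at least one descriptor")
        if self.weights.shape != (len(self.descriptor_names),):
            raise ValueError("one weight per descriptor required")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    @property
    def n(self) -> int:
        return len(self.descriptor_names)

    def score(self, ds: DescriptorDataset) -> np.ndarray:
        """Linear score per compound (higher = better rank)."""
        sub = ds.select_descriptors(self.descriptor_names)
        return sub.values @ self.weights

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "descriptor_names": list(self.descriptor_names),
            "weights": self.weights.tolist(),
            "n_descriptors": self.n,
            "metadata": self.metadata,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict) -> "EoaModel":
        return cls(
            descriptor_names=list(payload["descriptor_names"]),
            weights=np.asarray(payload["weights"], dtype=float),
            metadata=dict(payload.get("metadata", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EoaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RankedList:
    """Compounds ordered best-first by model score.

    Ties in score keep the input row order (stable sort), so a ranking is a
    deterministic function of (model, dataset).
    """

    compound_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())


def rank_compounds(model: EoaModel, ds: DescriptorDataset) -> RankedList:
    """Rank ``ds`` by the model's linear score, descending, stable on ties."""
    scores = model.score(ds)
    order = np.argsort(-scores, kind="stable")
    return RankedList(
        compound_ids=[ds.compound_ids[i] for i in order],
        scores=scores[order],
        labels=ds.labels[order],
    )


def _check_L(ranked: RankedList, L: int) -> None:
    if not 1 <= L <= len(ranked):
        raise ValueError(f"L={L} outside [1, {len(ranked)}]")
    if L != ranked.n_active:
        raise ValueError(
            f"objective is defined for L = number of actives "
            f"({ranked.n_active}), got L={L}"
        )


def primary_score(ranked: RankedList, L: int) -> int:
    """Number of actives within the first L places of the ranked list."""
    _check_L(ranked, L)
    return int(ranked.labels[:L].sum())


def _displacement(labels_ranked: np.ndarray, L: int) -> int:
    pos = np.arange(1, labels_ranked.size + 1)
    below = labels_ranked[L:]
    above = labels_ranked[:L]
    d_act = (pos[L:][below] - L).sum() if below.any() else 0
    d_dec = (L + 1 - pos[:L][~above]).sum() if (~above).any() else 0
    return int(d_act + d_dec)


def secondary_score(ranked: RankedList, L: int, tau: float) -> tuple[int, float]:
    """Displacement D and its inverse-sigmoid normalization into (0, 1].

    Returns ``(D, 2 / (1 + exp(D / tau)))``.  ``tau`` sets how fast credit
    decays with displacement; the default used elsewhere is tau = L.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    _check_L(ranked, L)
    D = _displacement(ranked.labels, L)
    return D, float(2.0 * expit(-D / tau))


@dataclass
class ObjectiveValue:
    """Primary count, displacement, secondary score and their combination."""

    primary: int
    displacement: int
    secondary: float
    total: float


def objective_value(
    ranked: RankedList, L: int, tau: Optional[float] = None
) -> ObjectiveValue:
    """Total objective = primary + secondary (default tau = L).

    Because secondary < 1 whenever separation is imperfect, any ranking with
    a higher primary count strictly dominates, regardless of displacement.
    """
    tau = float(L) if tau is None else float(tau)
    p = primary_score(ranked, L)
    D, s = secondary_score(ranked, L, tau)
    return ObjectiveValue(primary=p, displacement=D, secondary=s, total=p + s)


def _objective_from_scores(
    scores: np.ndarray, labels: np.ndarray, L: int, tau: float
) -> ObjectiveValue:
    # hot path of the optimizer: same math as objective_value without the
    # RankedList wrapper
    order = np.argsort(-scores, kind="stable")
    lab = labels[order]
    p = int(lab[:L].sum())
    D = _displacement(lab, L)
    s = float(2.0 * expit(-D / tau))
    return ObjectiveValue(primary=p, displacement=D, secondary=s, total=p + s)


@dataclass
class AnnealingSchedule:
    """Saw-tooth RT program for Metropolis acceptance.

    Within one cycle RT decreases linearly from ``rt_start`` to ``rt_end``
    in ``rt_step`` intervals, spending ``steps_per_interval`` MC steps on
    each rung; the cycle then restarts from ``rt_start``.  With the default
    values the ladder is 1.00, 0.99, ..., 0.01 (100 rungs), one cycle is
    40,000 steps, and the default budget of 1,000,000 steps spans 25 cycles.
    """

    rt_start: float = 1.0
    rt_end: float = 0.01
    rt_step: float = 0.01
    steps_per_interval: int = 400
    total_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if not self.rt_start > self.rt_end > 0:
            raise ValueError("require rt_start > rt_end > 0")
        if self.rt_step <= 0:
            raise ValueError("rt_step must be > 0")
        if self.steps_per_interval < 1:
            raise ValueError("steps_per_interval must be >= 1")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")

    @property
    def n_rungs(self) -> int:
        return int(math.floor((self.rt_start - self.rt_end) / self.rt_step + 1e-9)) + 1

    @property
    def ladder(self) -> np.ndarray:
        # rounded so that e.g. 1.0 - 99 * 0.01 prints (and compares) as 0.01
        return np.round(self.rt_start - self.rt_step * np.arange(self.n_rungs), 12)

    @property
    def cycle_steps(self) -> int:
        return self.n_rungs * self.steps_per_interval

    def rt_at(self, step: int) -> float:
        return float(self.ladder[(step % self.cycle_steps) // self.steps_per_interval])


@dataclass
class MoveConfig:
    """Proposal distribution of the MC search.

    A move either swaps one selected descriptor for a uniformly chosen
    unselected pool descriptor (the incoming weight is redrawn uniformly
    from ``weight_init_range``) or perturbs a single weight with additive
    Gaussian noise of standard deviation ``weight_sigma``.  Exactly one
    change per move.
    """

    swap_probability: float = 0.5
    weight_sigma: float = 0.1
    weight_init_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 <= self.swap_probability <= 1:
            raise ValueError("swap_probability must be in [0, 1]")
        if self.weight_sigma <= 0:
            raise ValueError("weight_sigma must be > 0")
        lo, hi = self.weight_init_range
        if not lo < hi:
            raise ValueError("weight_init_range must be an increasing pair")


def propose_move(
    model: EoaModel,
    pool: Sequence[str],
    cfg: MoveConfig,
    rng: np.random.Generator,
) -> EoaModel:
    """One elementary search move applied to a copy of ``model``.

    If every pool descriptor is already selected, the swap branch is
    unavailable and a weight perturbation is made instead.
    """
    pool = list(pool)
    n = model.n
    if len(pool) < n:
        raise ValueError(f"pool of {len(pool)} descriptors < model size {n}")
    missing = [nm for nm in model.descriptor_names if nm not in set(pool)]
    if missing:
        raise ValueError(f"model descriptors not in pool: {missing}")
    names = list(model.descriptor_names)
    weights = model.weights.copy()
    lo, hi = cfg.weight_init_range
    can_swap = len(pool) > n
    if can_swap and rng.random() < cfg.swap_probability:
        j = int(rng.integers(n))
        selected = set(names)
        unselected = [nm for nm in pool if nm not in selected]
        names[j] = unselected[int(rng.integers(len(unselected)))]
        weights[j] = rng.uniform(lo, hi)
    else:
        j = int(rng.integers(n))
        weights[j] = weights[j] + rng.normal(0.0, cfg.weight_sigma)
    return EoaModel(descriptor_names=names, weights=weights, metadata=dict(model.metadata))


@dataclass
class OptimizerTrace:
    """Per-interval progress record of one MC/SA run."""

    step: np.ndarray
    rt: np.ndarray
    current_total: np.ndarray
    best_total: np.ndarray
    acceptance_rate: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "rt": self.rt,
                "current_total": self.current_total,
                "best_total": self.best_total,
                "acceptance_rate": self.acceptance_rate,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), sep="\t", index=False)


def optimize(
    train: DescriptorDataset,
    n_descriptors: int,
    schedule: Optional[AnnealingSchedule] = None,
    moves: Optional[MoveConfig] = None,
    tau: Optional[float] = None,
    seed: int = 0,
    allowed_descriptors: Optional[Sequence[str]] = None,
) -> tuple[EoaModel, OptimizerTrace]:
    """Derive an EOA model by Metropolis MC under the saw-tooth schedule.

    Starting from a random descriptor subset with weights uniform in the
    move config's init range, each step proposes one elementary move and
    accepts it with probability ``min(1, exp(dTotal / RT))``.  The returned
    model is the best-so-far solution (highest total objective; ties keep
    the earliest), independent of where the chain ends.  The run is fully
    determined by (data, parameters, seed).

    Parameters
    ----------
    train
        Normalized training dataset with at least one active and one decoy.
    n_descriptors
        Model size (number of descriptors selected).
    allowed_descriptors
        Optional restricted candidate pool (e.g. a hand-picked shortlist);
        defaults to every descriptor in ``train``.
    tau
        Secondary-score decay scale; defaults to L, the number of actives.
    """
    schedule = schedule or AnnealingSchedule()
    moves = moves or MoveConfig()
    if allowed_descriptors is not None:
        pool_names = list(allowed_descriptors)
        missing = [nm for nm in pool_names if nm not in set(train.descriptor_names)]
        if missing:
            raise ValueError(f"allowed descriptors not in training data: {missing}")
    else:
        pool_names = list(train.descriptor_names)
    P = len(pool_names)
    if not 1 <= n_descriptors <= P:
        raise ValueError(
            f"n_descriptors={n_descriptors} infeasible for a pool of {P} descriptors"
        )
    if n_descriptors >= train.n_compounds:
        raise ValueError("need more training compounds than model descriptors")
    L = train.n_active
    if L < 1 or train.n_inactive < 1:
        raise ValueError("training set must contain both actives and inactives")
    tau_v = float(L) if tau is None else float(tau)
    if tau_v <= 0:
        raise ValueError("tau must be > 0")

    col_of = {nm: j for j, nm in enumerate(train.descriptor_names)}
    X = train.values[:, [col_of[nm] for nm in pool_names]]
    labels = train.labels
    n = n_descriptors
    lo, hi = moves.weight_init_range

    rng = np.random.default_rng(seed)
    sel = rng.permutation(P)[:n].copy()
    in_model = np.zeros(P, dtype=bool)
    in_model[sel] = True
    w = rng.uniform(lo, hi, size=n)
    scores = X[:, sel] @ w
    cur = _objective_from_scores(scores, labels, L, tau_v)
    if not math.isfinite(cur.total):
        raise ValueError("non-finite objective on initial model")
    best_total = cur.total
    best_obj = cur
    best_sel = sel.copy()
    best_w = w.copy()
    best_step = 0

    ladder = schedule.ladder
    spi = schedule.steps_per_interval
    cycle = schedule.cycle_steps
    can_swap = P > n

    t_step: list[int] = []
    t_rt: list[float] = []
    t_cur: list[float] = []
    t_best: list[float] = []
    t_acc: list[float] = []
    accepted_in_interval = 0
    steps_in_interval = 0

    for k in range(schedule.total_steps):
        rt = ladder[(k % cycle) // spi]
        if can_swap and rng.random() < moves.swap_probability:
            j = int(rng.integers(n))
            old_d, old_w = sel[j], w[j]
            unsel = np.flatnonzero(~in_model)
            new_d = int(unsel[int(rng.integers(unsel.size))])
            new_w = rng.uniform(lo, hi)
            delta = new_w * X[:, new_d] - old_w * X[:, old_d]
        else:
            j = int(rng.integers(n))
            old_d, old_w = sel[j], w[j]
            new_d = old_d
            new_w = old_w + rng.normal(0.0, moves.weight_sigma)
            delta = (new_w - old_w) * X[:, old_d]
        scores += delta
        cand = _objective_from_scores(scores, labels, L, tau_v)
        d_total = cand.total - cur.total
        accept = d_total >= 0 or rng.random() < math.exp(d_total / rt)
        if accept:
            if new_d != old_d:
                in_model[old_d] = False
                in_model[new_d] = True
                sel[j] = new_d
            w[j] = new_w
            cur = cand
            accepted_in_interval += 1
            if cur.total > best_total:
                best_total = cur.total
                best_obj = cur
                best_sel = sel.copy()
                best_w = w.copy()
                best_step = k + 1
        else:
            scores -= delta
        steps_in_interval += 1
        if (k + 1) % spi == 0 or k + 1 == schedule.total_steps:
            t_step.append(k + 1)
            t_rt.append(float(rt))
            t_cur.append(cur.total)
            t_best.append(best_total)
            t_acc.append(accepted_in_interval / steps_in_interval)
            accepted_in_interval = 0
            steps_in_interval = 0
        if (k + 1) % 4096 == 0:
            # re-anchor the incrementally updated scores against drift
            scores = X[:, sel] @ w
            cur = _objective_from_scores(scores, labels, L, tau_v)

    model = EoaModel(
        descriptor_names=[pool_names[i] for i in best_sel],
        weights=best_w,
        metadata={
            "seed": int(seed),
            "steps": int(schedule.total_steps),
            "tau": tau_v,
            "L": int(L),
            "best_step": int(best_step),
            "objective": {
                "primary": best_obj.primary,
                "displacement": best_obj.displacement,
                "secondary": best_obj.secondary,
                "total": best_obj.total,
            },
            "schedule": {
                "rt_start": schedule.rt_start,
                "rt_end": schedule.rt_end,
                "rt_step": schedule.rt_step,
                "steps_per_interval": schedule.steps_per_interval,
                "total_steps": schedule.total_steps,
            },
        },
    )
    trace = OptimizerTrace(
        step=np.asarray(t_step),
        rt=np.asarray(t_rt),
        current_total=np.asarray(t_cur),
        best_total=np.asarray(t_best),
        acceptance_rate=np.asarray(t_acc),
    )
    return model, trace
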