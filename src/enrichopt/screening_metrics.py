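"""Virtual-screening evaluation: ROC/AUC, enrichment factors, consensus.

The two headline metrics are the area under the ROC curve (overall ranking
quality; equals the probability that a random active outranks a random
decoy, with half credit for ties) and the enrichment factor at a library
fraction f,

    EF_f = (a / A) / f,

where A is the total number of actives and a the number found among the
top ``ceil(f * N)`` ranked compounds.  When several score columns are
available (e.g. docking scores against two crystal structures of the same
target), the consensus ranking takes each compound's most favorable score
across columns before computing metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .eoa_engine import EoaModel, rank_compounds
from .preprocessing import DescriptorDataset

__all__ = [
    "MetricsReport",
    "ScoreTable",
    "roc_curve",
    "auc",
    "enrichment_factor",
    "consensus_best_score",
    "evaluate_model",
    "load_score_table",
]


def _validate_binary(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and of equal length")
    if labels.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("need at least one active and one decoy")
    return labels, scores


def roc_curve(labels: Sequence, scores: Sequence) -> list[tuple[float, float]]:
    """ROC points (FPR, TPR) from a descending threshold sweep.

    Tied scores advance FPR and TPR jointly, producing one diagonal
    segment per tie group; the curve always starts at (0, 0) and ends at
    (1, 1).
    """
    labels, scores = _validate_binary(np.asarray(labels), np.asarray(scores))
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
    return [(float(x), float(y)) for x, y in zip(fpr, tpr)]


def auc(labels: Sequence, scores: Sequence) -> float:
    """Trapezoidal area under the ROC curve (tie-corrected Mann-Whitney)."""
    labels, scores = _validate_binary(np.asarray(labels), np.asarray(scores))
    return float(roc_auc_score(labels.astype(int), scores))


def enrichment_factor(
    labels: Sequence,
    scores: Sequence,
    fraction: float,
    higher_is_better: bool = True,
) -> float:
    """Enrichment factor EF_f = (a / A) / f.

    ``a`` counts actives among the top ``ceil(f * N)`` compounds of the
    ranked list (stable ties, ranking direction set by
    ``higher_is_better``); ``A`` is the total number of actives.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    A = int(labels.sum())
    if A == 0:
        raise ValueError("no active compounds in the list")
    N = labels.size
    n_top = math.ceil(fraction * N)
    key = -scores if higher_is_better else scores
    order = np.argsort(key, kind="stable")
    a = int(labels[order][:n_top].sum())
    return (a / A) / fraction


@dataclass
class ScoreTable:
    """Per-compound scores from one or more scoring runs (columns).

    ``higher_is_better`` fixes the ranking direction for every column;
    docking energies, for instance, are lower-is-better.
    """

    compound_ids: list[str]
    column_names: list[str]
    scores: np.ndarray  # (n_compounds, n_columns)
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if self.scores.shape != (len(self.compound_ids), len(self.column_names)):
            raise ValueError("scores shape must be (n_compounds, n_columns)")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids in score table")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, id_column: str = "id", higher_is_better: bool = True
    ) -> "ScoreTable":
        if id_column not in df.columns:
            raise ValueError(f"missing required column {id_column!r}")
        cols = [c for c in df.columns if c != id_column]
        if not cols:
            raise ValueError("score table has no score columns")
        return cls(
            compound_ids=df[id_column].astype(str).tolist(),
            column_names=cols,
            scores=df[cols].to_numpy(dtype=float),
            higher_is_better=higher_is_better,
        )

    @classmethod
    def merge(cls, tables: Sequence["ScoreTable"]) -> "ScoreTable":
        """Join tables column-wise; all must share the same id set and direction."""
        if not tables:
            raise ValueError("no score tables given")
        first = tables[0]
        ref = set(first.compound_ids)
        for t in tables[1:]:
            if t.higher_is_better != first.higher_is_better:
                raise ValueError("score tables disagree on ranking direction")
            other = set(t.compound_ids)
            if other != ref:
                only_first = sorted(ref - other)[:5]
                only_other = sorted(other - ref)[:5]
                raise ValueError(
                    "score tables cover different compounds; e.g. only in "
                    f"first: {only_first}, only in other: {only_other}"
                )
        pos = [{cid: i for i, cid in enumerate(t.compound_ids)} for t in tables]
        ids = list(first.compound_ids)
        blocks = [
            t.scores[[pos[k][cid] for cid in ids], :] for k, t in enumerate(tables)
        ]
        return cls(
            compound_ids=ids,
            column_names=[c for t in tables for c in t.column_names],
            scores=np.hstack(blocks),
            higher_is_better=first.higher_is_better,
        )


def load_score_table(
    path: str | Path, id_column: str = "id", higher_is_better: bool = True
) -> ScoreTable:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return ScoreTable.from_dataframe(
        pd.read_csv(path, sep=sep), id_column=id_column, higher_is_better=higher_is_better
    )


def consensus_best_score(table: ScoreTable) -> tuple[list[str], np.ndarray]:
    """Per compound, the most favorable score across columns.

    Max across columns when higher scores are better, min otherwise.
    Idempotent and invariant to column order.
    """
    best = table.scores.max(axis=1) if table.higher_is_better else table.scores.min(axis=1)
    return list(table.compound_ids), best


def _percent_half_up(count: int, total: int) -> int:
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class MetricsReport:
    """Screening metrics for one ranked list."""

    L: int
    top_L_count: int
    top_L_percent: int
    auc: float
    ef: dict[float, float]
    roc: list[tuple[float, float]]

    def to_dict(self) -> dict:
        return {
            "L": self.L,
            "top_L_count": self.top_L_count,
            "top_L_percent": self.top_L_percent,
            "auc": self.auc,
            "ef": {str(f): v for f, v in self.ef.items()},
            "roc": [[x, y] for x, y in self.roc],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def evaluate_model(
    model: EoaModel,
    ds: DescriptorDataset,
    fractions: Sequence[float] = (0.01,),
) -> MetricsReport:
    """Rank ``ds`` with ``model`` and report top-L recovery, AUC and EFs.

    L is the number of actives in ``ds``; the top-L percentage is rounded
    half-up to an integer.
    """
    if ds.n_active < 1 or ds.n_inactive < 1:
        raise ValueError("dataset must contain both actives and decoys")
    ranked = rank_compounds(model, ds)
    L = ds.n_active
    top = int(ranked.labels[:L].sum())
    scores = model.score(ds)
    return MetricsReport(
        L=L,
        top_L_count=top,
        top_L_percent=_percent_half_up(top, L),
        auc=auc(ds.labels, scores),
        ef={float(f): enrichment_factor(ds.labels, scores, float(f)) for f in fractions},
        roc=roc_curve(ds.labels, scores),
    )
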