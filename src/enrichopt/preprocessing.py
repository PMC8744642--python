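"""Descriptor-table I/O and preprocessing.

A virtual-screening dataset is a table of compounds (rows) by molecular
descriptors (columns), with a binary activity label per compound.  Before
model derivation the descriptor block is pruned — constant, nearly constant
and mutually correlated columns are dropped — and the survivors are brought
to a common scale by z-scoring.  The same scaler can later be applied to
out-of-sample compounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorDataset",
    "PreprocessConfig",
    "ScalerStats",
    "FilterRecord",
    "FilterReport",
    "load_descriptor_table",
    "save_descriptor_table",
    "filter_descriptors",
    "zscore_normalize",
]


@dataclass
class DescriptorDataset:
    """Compounds x descriptors matrix with per-compound activity labels.

    Parameters
    ----------
    compound_ids
        Unique compound identifiers, one per row.
    labels
        Boolean activity per compound (``True`` = active).
    descriptor_names
        Column names of the descriptor block.
    values
        Numeric matrix of shape ``(n_compounds, n_descriptors)``.  All
        entries must be finite.
    """

    compound_ids: list[str]
    labels: np.ndarray
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.labels = np.asarray(self.labels, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.compound_ids) != n:
            raise ValueError(
                f"{len(self.compound_ids)} ids for {n} rows of descriptor values"
            )
        if self.labels.shape != (n,):
            raise ValueError(f"{self.labels.size} labels for {n} compounds")
        if len(self.descriptor_names) != d:
            raise ValueError(
                f"{len(self.descriptor_names)} descriptor names for {d} columns"
            )
        seen: set[str] = set()
        for cid in self.compound_ids:
            if cid in seen:
                raise ValueError(f"duplicate compound id {cid!r}")
            seen.add(cid)
        if len(set(self.descriptor_names)) != d:
            raise ValueError("duplicate descriptor names")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite descriptor value at row {bad[0]} "
                f"(compound {self.compound_ids[bad[0]]!r}), "
                f"column {self.descriptor_names[bad[1]]!r}"
            )

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def n_active(self) -> int:
        return int(self.labels.sum())

    @property
    def n_inactive(self) -> int:
        return int((~self.labels).sum())

    def __len__(self) -> int:
        return self.n_compounds

    # -- derived views ---------------------------------------------------------
    def subset_rows(self, indices: Sequence[int]) -> "DescriptorDataset":
        """Row-subset view (copy) preserving the given order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return DescriptorDataset(
            compound_ids=[self.compound_ids[i] for i in idx],
            labels=self.labels[idx],
            descriptor_names=list(self.descriptor_names),
            values=self.values[idx],
        )

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorDataset":
        """Column subset in the order of ``names``; unknown names are an error."""
        pos = {nm: j for j, nm in enumerate(self.descriptor_names)}
        missing = [nm for nm in names if nm not in pos]
        if missing:
            raise ValueError(f"descriptors not present in dataset: {missing}")
        cols = [pos[nm] for nm in names]
        return DescriptorDataset(
            compound_ids=list(self.compound_ids),
            labels=self.labels.copy(),
            descriptor_names=list(names),
            values=self.values[:, cols],
        )

    def with_labels(self, labels: np.ndarray) -> "DescriptorDataset":
        return DescriptorDataset(
            compound_ids=list(self.compound_ids),
            labels=np.asarray(labels, dtype=bool),
            descriptor_names=list(self.descriptor_names),
            values=self.values.copy(),
        )

    # -- I/O -------------------------------------------------------------------
    def to_dataframe(
        self,
        id_column: str = "id",
        label_column: str = "label",
        active_token: str = "active",
        inactive_token: str = "inactive",
    ) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, label_column, np.where(self.labels, active_token, inactive_token))
        df.insert(0, id_column, self.compound_ids)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_column: str = "id",
        label_column: str = "label",
        active_token: str = "active",
    ) -> "DescriptorDataset":
        for col in (id_column, label_column):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        descriptor_cols = [c for c in df.columns if c not in (id_column, label_column)]
        values = np.empty((len(df), len(descriptor_cols)), dtype=float)
        for j, col in enumerate(descriptor_cols):
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"non-numeric descriptor value {df[col].iloc[row]!r} "
                    f"at row {row}, column {col!r}"
                )
            values[:, j] = numeric.to_numpy(dtype=float)
        labels = (df[label_column].astype(str) == active_token).to_numpy()
        return cls(
            compound_ids=df[id_column].astype(str).tolist(),
            labels=labels,
            descriptor_names=descriptor_cols,
            values=values,
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_descriptor_table(
    path: str | Path,
    id_column: str = "id",
    label_column: str = "label",
    active_token: str = "active",
) -> DescriptorDataset:
    """Read a delimited descriptor table (CSV/TSV chosen by extension).

    The table must have a header row, one id column, one label column and
    any number of numeric descriptor columns.  Rows keep their file order;
    a label equal to ``active_token`` marks a compound active, anything
    else inactive.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return DescriptorDataset.from_dataframe(
        df, id_column=id_column, label_column=label_column, active_token=active_token
    )


def save_descriptor_table(
    ds: DescriptorDataset,
    path: str | Path,
    id_column: str = "id",
    label_column: str = "label",
    active_token: str = "active",
    inactive_token: str = "inactive",
) -> None:
    path = Path(path)
    ds.to_dataframe(id_column, label_column, active_token, inactive_token).to_csv(
        path, sep=_sep_for(path), index=False
    )


@dataclass
class PreprocessConfig:
    """Descriptor-pruning thresholds.

    ``r2_threshold`` drops the later member of any column pair whose squared
    Pearson correlation exceeds it; ``near_constant_fraction`` drops columns
    whose single most frequent value covers at least that fraction of the
    compounds (a fully constant column is the limiting case).
    """

    r2_threshold: float = 0.7
    near_constant_fraction: float = 0.7
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if not 0 < self.near_constant_fraction <= 1:
            raise ValueError("near_constant_fraction must be in (0, 1]")


@dataclass
class FilterRecord:
    column: str
    rule: str  # "constant" | "near_constant" | "correlated"
    detail: str


@dataclass
class FilterReport:
    removed: list[FilterRecord]
    kept: list[str]
    config: PreprocessConfig

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.column, r.rule, r.detail) for r in self.removed],
            columns=["column", "rule", "detail"],
        )

    def save(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), sep="\t", index=False)


def filter_descriptors(
    ds: DescriptorDataset, cfg: Optional[PreprocessConfig] = None
) -> tuple[DescriptorDataset, FilterReport]:
    """Drop constant, nearly constant and pairwise-correlated descriptors.

    The constant / near-constant pass runs first (correlation is undefined
    against a zero-variance column).  The correlation pass is greedy in
    table order: the earlier column of a violating pair is kept, the later
    one dropped, so the result is deterministic for a given column order.
    """
    cfg = cfg or PreprocessConfig()
    if ds.n_descriptors == 0 or ds.n_compounds == 0:
        raise ValueError("empty dataset")

    removed: list[FilterRecord] = []
    survivors: list[int] = []
    n = ds.n_compounds
    for j, name in enumerate(ds.descriptor_names):
        col = ds.values[:, j]
        uniques, counts = np.unique(col, return_counts=True)
        modal_fraction = counts.max() / n
        if uniques.size == 1:
            removed.append(FilterRecord(name, "constant", f"single value {uniques[0]!r}"))
        elif modal_fraction >= cfg.near_constant_fraction:
            removed.append(
                FilterRecord(
                    name,
                    "near_constant",
                    f"modal value covers {modal_fraction:.4f} >= "
                    f"{cfg.near_constant_fraction}",
                )
            )
        else:
            survivors.append(j)

    if survivors:
        sub = ds.values[:, survivors]
        with np.errstate(invalid="ignore"):
            r2 = np.corrcoef(sub, rowvar=False) ** 2
        r2 = np.atleast_2d(r2)
        kept_local: list[int] = []
        for a, j in enumerate(survivors):
            partner = None
            for b in kept_local:
                if r2[b, a] > cfg.r2_threshold:
                    partner = b
                    break
            if partner is None:
                kept_local.append(a)
            else:
                removed.append(
                    FilterRecord(
                        ds.descriptor_names[j],
                        "correlated",
                        f"r2 = {r2[partner, a]:.4f} > {cfg.r2_threshold} with "
                        f"{ds.descriptor_names[survivors[partner]]!r}",
                    )
                )
        kept_idx = [survivors[b] for b in kept_local]
    else:
        kept_idx = []

    if not kept_idx:
        raise ValueError("no descriptors survive filtering")

    kept_names = [ds.descriptor_names[j] for j in kept_idx]
    out = ds.select_descriptors(kept_names)
    return out, FilterReport(removed=removed, kept=kept_names, config=cfg)


@dataclass
class ScalerStats:
    """Per-descriptor mean and standard deviation used for z-scoring.

    The standard deviation is the population form (divide by *n*); ranking
    by a linear model is invariant to that convention.
    """

    descriptor_names: list[str]
    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        d = len(self.descriptor_names)
        if self.mean.shape != (d,) or self.std.shape != (d,):
            raise ValueError("mean/std must have one entry per descriptor")
        if not (self.std > 0).all():
            bad = self.descriptor_names[int(np.argmin(self.std))]
            raise ValueError(f"non-positive standard deviation for {bad!r}")

    def save(self, path: str | Path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScalerStats":
        payload = json.loads(Path(path).read_text())
        return cls(
            descriptor_names=list(payload["descriptor_names"]),
            mean=np.asarray(payload["mean"], dtype=float),
            std=np.asarray(payload["std"], dtype=float),
        )


def zscore_normalize(
    ds: DescriptorDataset, stats: Optional[ScalerStats] = None
) -> tuple[DescriptorDataset, ScalerStats]:
    """Z-score the descriptor block.

    With ``stats=None`` the mean and population standard deviation are
    fitted on ``ds`` itself; otherwise the supplied statistics are applied
    unchanged, which is how held-out compounds are brought onto the scale
    of a training set.
    """
    if stats is None:
        mean = ds.values.mean(axis=0)
        std = ds.values.std(axis=0)
        zero = np.flatnonzero(std == 0)
        if zero.size:
            raise ValueError(
                f"zero spread in column {ds.descriptor_names[int(zero[0])]!r}; "
                "filter constant descriptors first"
            )
        stats = ScalerStats(list(ds.descriptor_names), mean, std)
    else:
        if list(stats.descriptor_names) != list(ds.descriptor_names):
            raise ValueError("scaler statistics do not match dataset descriptors")
    transformed = (ds.values - stats.mean) / stats.std
    out = DescriptorDataset(
        compound_ids=list(ds.compound_ids),
        labels=ds.labels.copy(),
        descriptor_names=list(ds.descriptor_names),
        values=transformed,
    )
    return out, stats
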