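"""Tabular data model shared by every stage of the toolkit.

A monitoring table is an information system: ``n`` water samples described by
``d`` continuous condition attributes (water level, flow, chemistry, ...) and
one continuous decision attribute, here the chlorophyll quantity of a single
algal phylum.  :class:`SampleTable` is the in-memory form; CSV is the on-disk
form.  The module also owns the three pieces of plumbing every downstream
stage needs: min–max normalization with retained scaling parameters,
quantile discretization of the continuous target (granular-ball purity needs
class labels), and seeded cross-validation fold plans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleTable",
    "DiscretizedTarget",
    "FoldPlan",
    "MinMaxParams",
    "read_table",
    "write_table",
    "min_max_normalize",
    "fit_min_max",
    "apply_min_max",
    "discretize_target",
    "make_folds",
    "iter_folds",
]


@dataclass
class SampleTable:
    """An ``n x d`` condition-attribute matrix plus one decision attribute.

    Parameters
    ----------
    values
        Real-valued condition attributes, shape ``(n, d)``.
    target
        Decision-attribute values, shape ``(n,)``.
    attribute_names
        ``d`` column labels.
    sample_ids
        ``n`` row labels.
    """

    values: np.ndarray
    target: np.ndarray
    attribute_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(-1, 1)
        self.target = np.asarray(self.target, dtype=float).ravel()
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("SampleTable requires n >= 1 and d >= 1")
        if self.target.shape[0] != n:
            raise ValueError(
                f"target length {self.target.shape[0]} != number of rows {n}"
            )
        if not self.attribute_names:
            self.attribute_names = [f"attr_{j + 1}" for j in range(d)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1:03d}" for i in range(n)]
        if len(self.attribute_names) != d:
            raise ValueError("attribute_names length mismatch")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if not np.isfinite(self.values).all() or not np.isfinite(self.target).all():
            raise ValueError("SampleTable must not contain missing/non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def subset_attributes(self, indices: Sequence[int]) -> "SampleTable":
        """Table restricted to the given condition-attribute columns."""
        idx = list(indices)
        return SampleTable(
            values=self.values[:, idx],
            target=self.target.copy(),
            attribute_names=[self.attribute_names[j] for j in idx],
            sample_ids=list(self.sample_ids),
        )

    def subset_rows(self, indices: Sequence[int]) -> "SampleTable":
        """Table restricted to the given sample rows."""
        idx = np.asarray(list(indices), dtype=int)
        return SampleTable(
            values=self.values[idx],
            target=self.target[idx],
            attribute_names=list(self.attribute_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def to_frame(self, target_column: str = "target") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.attribute_names)
        df[target_column] = self.target
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class DiscretizedTarget:
    """Integer class codes obtained by quantile-binning the decision attribute."""

    labels: np.ndarray
    bin_edges: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class FoldPlan:
    """Deterministic assignment of each sample to one cross-validation fold."""

    fold_assignments: np.ndarray
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        self.fold_assignments = np.asarray(self.fold_assignments, dtype=int)


def read_table(path: str | Path, target_column: str) -> SampleTable:
    """Load a header-bearing CSV into a :class:`SampleTable`.

    All columns other than ``target_column`` (and an optional ``sample_id``
    column) become condition attributes.  Rows with missing or non-numeric
    cells are dropped; the count is logged at WARNING level.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the target column is absent or no usable rows remain.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, float_precision="round_trip")
    if target_column not in df.columns:
        raise ValueError(f"target column {target_column!r} not found in {path}")
    sample_ids = None
    if "sample_id" in df.columns and target_column != "sample_id":
        sample_ids = df.pop("sample_id").astype(str).tolist()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("read_table: dropped %d row(s) with missing/non-numeric cells", dropped)
    numeric = numeric[keep]
    if numeric.shape[0] == 0:
        raise ValueError(f"no usable rows in {path} (all rows had missing cells)")
    target = numeric.pop(target_column).to_numpy(dtype=float)
    if numeric.shape[1] == 0:
        raise ValueError("no condition attributes remain besides the target column")
    ids = (
        [sample_ids[i] for i in np.flatnonzero(keep.to_numpy())]
        if sample_ids is not None
        else [f"s{i + 1:03d}" for i in range(numeric.shape[0])]
    )
    return SampleTable(
        values=numeric.to_numpy(dtype=float),
        target=target,
        attribute_names=[str(c) for c in numeric.columns],
        sample_ids=ids,
    )


def write_table(table: SampleTable, path: str | Path, target_column: str = "target") -> None:
    """Write a table as RFC-4180 CSV; values round-trip at full float precision."""
    # %.17g is the shortest format guaranteed to round-trip IEEE doubles
    table.to_frame(target_column).to_csv(path, index=False, float_format="%.17g")


@dataclass
class MinMaxParams:
    """Per-attribute scaling parameters fitted on training data.

    ``span`` is 1 for constant attributes so they map to 0 everywhere.
    """

    minimum: np.ndarray
    span: np.ndarray


def fit_min_max(values: np.ndarray) -> MinMaxParams:
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    span = np.where(span == 0.0, 1.0, span)
    return MinMaxParams(minimum=lo, span=span)


def apply_min_max(values: np.ndarray, params: MinMaxParams) -> np.ndarray:
    return (np.asarray(values, dtype=float) - params.minimum) / params.span


def min_max_normalize(
    table: SampleTable, params: MinMaxParams | None = None
) -> tuple[SampleTable, MinMaxParams]:
    """Rescale each condition attribute to ``[0, 1]``; the target is untouched.

    When ``params`` is given (fitted on training data) it is applied as-is, so
    test samples use training-set scaling.  Returns the scaled table together
    with the parameters used.
    """
    if params is None:
        params = fit_min_max(table.values)
    scaled = SampleTable(
        values=apply_min_max(table.values, params),
        target=table.target.copy(),
        attribute_names=list(table.attribute_names),
        sample_ids=list(table.sample_ids),
    )
    return scaled, params


def discretize_target(table: SampleTable | np.ndarray, q: int = 3) -> DiscretizedTarget:
    """Quantile-bin the decision attribute into ``q`` classes.

    Boundary values fall in the lower bin.  If fewer than ``q`` distinct
    target values exist, ``q`` is reduced to that count with a warning.
    """
    if q < 2:
        raise ValueError("q must be >= 2")
    t = table.target if isinstance(table, SampleTable) else np.asarray(table, dtype=float)
    n_distinct = np.unique(t).size
    if n_distinct < q:
        logger.warning(
            "discretize_target: only %d distinct target value(s); reducing q from %d",
            n_distinct,
            q,
        )
        q = max(n_distinct, 1)
    if q == 1:
        return DiscretizedTarget(labels=np.zeros(t.size, dtype=int), bin_edges=np.empty(0), q=1)
    edges = np.quantile(t, np.arange(1, q) / q)
    edges = np.unique(edges)
    # side="left": a value equal to an edge is counted in the lower bin
    labels = np.searchsorted(edges, t, side="left")
    return DiscretizedTarget(labels=labels, bin_edges=edges, q=edges.size + 1)


def make_folds(n: int, n_folds: int, seed: int) -> FoldPlan:
    """Balanced random fold assignment, deterministic for a fixed seed."""
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must satisfy 2 <= n_folds <= n (got {n_folds}, n={n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    assignments[perm] = np.arange(n) % n_folds
    return FoldPlan(fold_assignments=assignments, n_folds=n_folds, seed=seed)


def iter_folds(plan: FoldPlan) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield ``(train_indices, test_indices)`` for each fold in order."""
    for f in range(plan.n_folds):
        test = np.flatnonzero(plan.fold_assignments == f)
        train = np.flatnonzero(plan.fold_assignments != f)
        yield train, test
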