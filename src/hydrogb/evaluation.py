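"""Metrics, leakage-free cross-validated scoring, and the method harness.

Four error measures summarise one prediction run (actuals T, predictions T'):

    RMSE = sqrt(mean (T' - T)^2)
    MAE  = mean |T' - T|
    MAPE = 100% * mean |(T' - T) / T|   over samples with T != 0
    R^2  = 1 - SSE / SST                with SST about the mean of T

Six method pipelines are compared: plain kNN and BP (no selection), PK and
PBP (Pearson-sweep selection feeding kNN / BP), GBRSK and GBRSBP
(granular-ball rough-set reduction feeding kNN / BP).  All evaluation is
pooled over held-out folds, and any feature selection is refit inside each
training fold so held-out targets are never inspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import FoldPlan, SampleTable, discretize_target, iter_folds, make_folds
from .regressors import DEFAULT_K_GRID, KNNConfig, MLPConfig, fit_knn, knn_predict, mlp_predict, mlp_train

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport",
    "SelectorConfig",
    "EvalConfig",
    "ExperimentGrid",
    "compute_metrics",
    "knn_cv_rmse_grid",
    "mlp_cv_rmse",
    "cross_validated_score",
    "run_method",
    "write_report",
    "write_metrics_report",
    "METHODS",
]

METHODS = ("knn", "pk", "gbrsk", "bp", "pbp", "gbrsbp")


@dataclass
class MetricReport:
    """RMSE / MAE / MAPE / R-squared for one prediction run."""

    rmse: float
    mae: float
    mape: float
    r2: float
    n_evaluated: int
    mape_excluded: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"RMSE": self.rmse, "MAE": self.mae, "MAPE": self.mape, "R2": self.r2}


@dataclass(frozen=True)
class SelectorConfig:
    """Which feature-selection stage to run before the regressor.

    method
        "none", "pearson" (ranked-removal sweep) or "gbrs" (forward reduction).
    q
        Quantile bins used to discretize the target for ball purity (GBRS only).
    remove_largest_first
        Pearson sweep order: the verbatim reading deletes the largest-|rho|
        attributes first; the default deletes the smallest first.
    """

    method: str = "none"
    q: int = 3
    purity_threshold: float = 1.0
    min_size: int = 1
    count_singletons: bool = False
    remove_largest_first: bool = False

    def __post_init__(self) -> None:
        if self.method not in ("none", "pearson", "gbrs"):
            raise ValueError(f"unknown selector method {self.method!r}")


@dataclass(frozen=True)
class EvalConfig:
    """Cross-validation protocol: 5 folds by default, seeded."""

    n_folds: int = 5
    seed: int = 20240223
    holdout: float | None = None  # e.g. 0.3 for a single train/test split


@dataclass
class ExperimentGrid:
    """Per-cell scores of one method over (feature set, k) combinations.

    ``scores`` has one row per entry of ``feature_counts`` and one column per
    entry of ``k_grid`` (a single column for the BP family).
    """

    method: str
    k_grid: tuple[int, ...]
    feature_counts: list[int]
    scores: np.ndarray
    seed: int
    details: dict = field(default_factory=dict)

    def best_cell(self) -> tuple[int, int]:
        """(row, col) of the minimum score; first occurrence on ties."""
        return tuple(np.unravel_index(int(np.argmin(self.scores)), self.scores.shape))  # type: ignore[return-value]


def compute_metrics(actual: np.ndarray, predicted: np.ndarray) -> MetricReport:
    """Evaluate the four error measures for one prediction run.

    MAPE is computed over samples with nonzero actuals and the exclusion
    count recorded; it is an error for *all* actuals to be zero, as is zero
    variance in the actuals for R-squared.
    """
    T = np.asarray(actual, dtype=float).ravel()
    P = np.asarray(predicted, dtype=float).ravel()
    if T.size != P.size or T.size < 1:
        raise ValueError("actual and predicted must have equal length >= 1")
    resid = P - T
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    nonzero = T != 0.0
    excluded = int((~nonzero).sum())
    if excluded == T.size:
        raise ValueError("MAPE undefined: all actual values are zero")
    mape = float(100.0 * np.mean(np.abs(resid[nonzero] / T[nonzero])))
    sst = float(np.sum((T - T.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R^2 undefined: actual values have zero variance")
    r2 = float(1.0 - np.sum(resid**2) / sst)
    return MetricReport(
        rmse=rmse, mae=mae, mape=mape, r2=r2, n_evaluated=T.size, mape_excluded=excluded
    )


def _resolve_plan(table: SampleTable, evaluation: EvalConfig) -> FoldPlan:
    if evaluation.holdout is not None:
        # a single holdout split expressed as a 2-"fold" plan with unequal roles
        rng = np.random.default_rng(evaluation.seed)
        n_test = max(1, int(round(evaluation.holdout * table.n)))
        assignments = np.ones(table.n, dtype=int)
        assignments[rng.permutation(table.n)[:n_test]] = 0
        return FoldPlan(fold_assignments=assignments, n_folds=1, seed=evaluation.seed)
    return make_folds(table.n, evaluation.n_folds, evaluation.seed)


def _holdout_iter(plan: FoldPlan):
    if plan.n_folds == 1:  # holdout: fold 0 is the test set
        test = np.flatnonzero(plan.fold_assignments == 0)
        train = np.flatnonzero(plan.fold_assignments != 0)
        yield train, test
    else:
        yield from iter_folds(plan)


def knn_cv_rmse_grid(
    table: SampleTable,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    evaluation: EvalConfig = EvalConfig(),
    normalize: bool = True,
    plan: FoldPlan | None = None,
) -> np.ndarray:
    """Pooled out-of-fold RMSE of plain kNN for every k in the grid."""
    plan = plan if plan is not None else _resolve_plan(table, evaluation)
    actual: list[np.ndarray] = []
    per_k: dict[int, list[np.ndarray]] = {k: [] for k in k_grid}
    for train, test in _holdout_iter(plan):
        tr, te = table.subset_rows(train), table.subset_rows(test)
        actual.append(te.target)
        for k in k_grid:
            kk = min(k, tr.n)
            model = fit_knn(tr, kk, normalize=normalize)
            per_k[k].append(np.atleast_1d(knn_predict(model, te.values)))
    T = np.concatenate(actual)
    out = np.empty(len(k_grid))
    for i, k in enumerate(k_grid):
        P = np.concatenate(per_k[k])
        out[i] = float(np.sqrt(np.mean((P - T) ** 2)))
    return out


def mlp_cv_rmse(
    table: SampleTable,
    config: MLPConfig = MLPConfig(),
    evaluation: EvalConfig = EvalConfig(),
    plan: FoldPlan | None = None,
) -> float:
    """Pooled out-of-fold RMSE of the BP network."""
    plan = plan if plan is not None else _resolve_plan(table, evaluation)
    actual: list[np.ndarray] = []
    preds: list[np.ndarray] = []
    for train, test in _holdout_iter(plan):
        tr, te = table.subset_rows(train), table.subset_rows(test)
        model = mlp_train(tr, config)
        actual.append(te.target)
        preds.append(np.atleast_1d(mlp_predict(model, te.values)))
    T, P = np.concatenate(actual), np.concatenate(preds)
    return float(np.sqrt(np.mean((P - T) ** 2)))


def _select_features(
    train: SampleTable,
    selector: SelectorConfig,
    regressor: KNNConfig | MLPConfig,
    evaluation: EvalConfig,
) -> list[int]:
    """Run the configured selection stage on training data only."""
    if selector.method == "none":
        return list(range(train.d))
    if selector.method == "pearson":
        from .pearson import rank_attributes, sweep_select

        ranking = rank_attributes(train)
        sweep = sweep_select(
            train,
            ranking,
            regressor=regressor,
            evaluation=evaluation,
            remove_largest_first=selector.remove_largest_first,
        )
        return list(sweep.best_subset)
    from .gbrs import GBRSParams, forward_select

    labels = discretize_target(train, q=selector.q)
    result = forward_select(
        train,
        labels,
        params=GBRSParams(
            purity_threshold=selector.purity_threshold, min_size=selector.min_size
        ),
        count_singletons=selector.count_singletons,
    )
    if not result.selected:
        logger.warning("GBRS selected no attributes; falling back to all %d", train.d)
        return list(range(train.d))
    return result.selected


def cross_validated_score(
    table: SampleTable,
    selector: SelectorConfig = SelectorConfig(),
    regressor: KNNConfig | MLPConfig = KNNConfig(),
    evaluation: EvalConfig = EvalConfig(),
) -> MetricReport:
    """Pooled held-out metrics with selection refit inside each training fold."""
    plan = _resolve_plan(table, evaluation)
    actual: list[np.ndarray] = []
    preds: list[np.ndarray] = []
    selected_per_fold: list[list[int]] = []
    for train, test in _holdout_iter(plan):
        tr, te = table.subset_rows(train), table.subset_rows(test)
        feats = _select_features(tr, selector, regressor, evaluation)
        selected_per_fold.append(feats)
        tr_s, te_s = tr.subset_attributes(feats), te.subset_attributes(feats)
        if isinstance(regressor, KNNConfig):
            model = fit_knn(tr_s, min(regressor.k, tr_s.n), normalize=regressor.normalize)
            p = knn_predict(model, te_s.values)
        else:
            model = mlp_train(tr_s, regressor)
            p = mlp_predict(model, te_s.values)
        actual.append(te.target)
        preds.append(np.atleast_1d(p))
    report = compute_metrics(np.concatenate(actual), np.concatenate(preds))
    report.selected_per_fold = selected_per_fold  # type: ignore[attr-defined]
    return report


def _pearson_grid(
    table: SampleTable,
    k_grid: tuple[int, ...],
    evaluation: EvalConfig,
    normalize: bool,
    remove_largest_first: bool,
) -> tuple[np.ndarray, list[int]]:
    """Full (feature count x k) pooled-RMSE grid of the Pearson sweep.

    Rankings are computed per training fold, so the size-s subset may differ
    between folds; no held-out information enters the selection.
    """
    from .pearson import rank_attributes, removal_order

    plan = _resolve_plan(table, evaluation)
    d = table.d
    sizes = list(range(d, 0, -1))
    actual: list[np.ndarray] = []
    per_cell: dict[tuple[int, int], list[np.ndarray]] = {
        (s, k): [] for s in sizes for k in k_grid
    }
    for train, test in _holdout_iter(plan):
        tr, te = table.subset_rows(train), table.subset_rows(test)
        actual.append(te.target)
        ranking = rank_attributes(tr)
        order = removal_order(ranking, remove_largest_first)
        subset = list(range(d))
        for s in sizes:
            tr_s, te_s = tr.subset_attributes(subset), te.subset_attributes(subset)
            for k in k_grid:
                model = fit_knn(tr_s, min(k, tr_s.n), normalize=normalize)
                per_cell[(s, k)].append(np.atleast_1d(knn_predict(model, te_s.values)))
            if s > 1:
                subset = [a for a in subset if a != order[d - s]]
    T = np.concatenate(actual)
    scores = np.empty((len(sizes), len(k_grid)))
    for i, s in enumerate(sizes):
        for j, k in enumerate(k_grid):
            P = np.concatenate(per_cell[(s, k)])
            scores[i, j] = float(np.sqrt(np.mean((P - T) ** 2)))
    return scores, sizes


def run_method(
    table: SampleTable,
    method: str,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    selector: SelectorConfig | None = None,
    mlp_config: MLPConfig | None = None,
    evaluation: EvalConfig = EvalConfig(),
    normalize: bool = True,
) -> ExperimentGrid:
    """Run one of the six pipelines and return its score grid.

    kNN / BP use all features; PK / PBP run the Pearson ranked-removal sweep;
    GBRSK / GBRSBP run the granular-ball reduction.  kNN-family methods score
    every k in the grid; BP-family methods produce a single column.
    """
    method = method.lower()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    mlp_config = mlp_config or MLPConfig()
    details: dict = {}

    if method == "knn":
        scores = knn_cv_rmse_grid(table, k_grid, evaluation, normalize=normalize)
        return ExperimentGrid(method, k_grid, [table.d], scores.reshape(1, -1), evaluation.seed)

    if method == "pk":
        sel = selector or SelectorConfig(method="pearson")
        scores, sizes = _pearson_grid(
            table, k_grid, evaluation, normalize, sel.remove_largest_first
        )
        grid = ExperimentGrid(method, k_grid, sizes, scores, evaluation.seed)
        i, j = grid.best_cell()
        grid.details["best_feature_count"] = sizes[i]
        grid.details["best_k"] = k_grid[j]
        grid.details["per_k_best"] = scores.min(axis=0).tolist()
        return grid

    if method == "gbrsk":
        sel = selector or SelectorConfig(method="gbrs")
        scores = np.empty((1, len(k_grid)))
        reports = []
        for j, k in enumerate(k_grid):
            rep = cross_validated_score(table, sel, KNNConfig(k=k, normalize=normalize), evaluation)
            scores[0, j] = rep.rmse
            reports.append(rep)
        details["selected_per_fold"] = getattr(reports[0], "selected_per_fold", None)
        counts = [len(s) for s in details["selected_per_fold"] or []]
        feature_count = int(round(np.median(counts))) if counts else table.d
        return ExperimentGrid(method, k_grid, [feature_count], scores, evaluation.seed, details)

    # BP family: single-column grids
    if method == "bp":
        rep = cross_validated_score(table, SelectorConfig(), mlp_config, evaluation)
    elif method == "pbp":
        rep = cross_validated_score(
            table, selector or SelectorConfig(method="pearson"), mlp_config, evaluation
        )
    else:  # gbrsbp
        rep = cross_validated_score(
            table, selector or SelectorConfig(method="gbrs"), mlp_config, evaluation
        )
    details["report"] = rep
    sel_folds = getattr(rep, "selected_per_fold", None)
    counts = [len(s) for s in sel_folds or []]
    feature_count = int(round(np.median(counts))) if counts else table.d
    return ExperimentGrid(
        method, (), [feature_count], np.array([[rep.rmse]]), evaluation.seed, details
    )


def write_report(grid: ExperimentGrid, path: str | Path, round_integers: bool = False) -> None:
    """Write a score grid as CSV: rows = feature counts (descending), columns = k.

    The best (minimum) cell is flagged with a trailing ``*``.  With
    ``round_integers`` scores print as integers, matching the style of
    published comparison tables.
    """
    if grid.scores.size == 0:
        raise ValueError("empty grid")
    bi, bj = grid.best_cell()
    cols = [f"k={k}" for k in grid.k_grid] if grid.k_grid else ["RMSE"]
    lines = ["features," + ",".join(cols)]
    for i, s in enumerate(grid.feature_counts):
        cells = []
        for j in range(grid.scores.shape[1]):
            v = grid.scores[i, j]
            text = f"{v:.0f}" if round_integers else f"{v:.6g}"
            if (i, j) == (bi, bj):
                text += "*"
            cells.append(text)
        lines.append(f"{s}," + ",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def write_metrics_report(
    reports: Mapping[str, MetricReport], path: str | Path, round_integers: bool = False
) -> None:
    """Write a method-comparison CSV with columns RMSE, MAE, MAPE, R2."""
    if not reports:
        raise ValueError("no reports to write")
    lines = ["method,RMSE,MAE,MAPE,R2"]
    best = min(reports, key=lambda m: reports[m].rmse)
    for name, rep in reports.items():
        rmse = f"{rep.rmse:.0f}" if round_integers else f"{rep.rmse:.6g}"
        if name == best:
            rmse += "*"
        lines.append(f"{name},{rmse},{rep.mae:.6g},{rep.mape:.6g},{rep.r2:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
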