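"""Pearson-correlation feature ranking and the ranked-removal sweep.

The correlation of each condition attribute with the decision attribute is
computed with population (1/n) moments:

    E(X) = (1/n) sum X_i
    Cov(X, Y) = (1/n) sum (X_i - E(X)) (Y_i - E(Y))
    sigma_X = sqrt((1/n) sum (X_i - E(X))^2)
    rho_XY = Cov(X, Y) / (sigma_X sigma_Y)

|rho| <= 1 always, with equality exactly for affine pairs Y = aX + b (sign of
a gives the sign of rho).  The sweep then deletes one attribute at a time in
ranking order, scores the regressor at every nested subset size (for kNN,
minimising pooled CV RMSE over the k grid), and returns the size whose score
is lowest.

By default the *least* correlated attribute is removed first, which is the
conventional reading of correlation-guided elimination; the verbatim
alternative — deleting the largest-|rho| attributes first — is available via
``remove_largest_first=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import SampleTable
from .evaluation import EvalConfig, knn_cv_rmse_grid, mlp_cv_rmse
from .regressors import KNNConfig, MLPConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRanking",
    "SweepResult",
    "population_mean",
    "population_covariance",
    "population_std",
    "pearson_r",
    "rank_attributes",
    "removal_order",
    "sweep_select",
]


def population_mean(x: np.ndarray) -> float:
    return float(np.mean(np.asarray(x, dtype=float)))


def population_covariance(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean((x - x.mean()) * (y - y.mean())))


def population_std(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Population Pearson correlation coefficient of two equal-length vectors.

    Raises ``ValueError`` when either vector has zero variance (the
    coefficient is undefined there).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("pearson_r requires two vectors of equal length >= 2")
    sx, sy = population_std(x), population_std(y)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("pearson_r undefined: zero variance input")
    return population_covariance(x, y) / (sx * sy)


@dataclass
class CorrelationRanking:
    """Per-attribute rho with the decision attribute, sorted by |rho|."""

    coefficients: np.ndarray
    order: np.ndarray  # attribute indices, descending |rho| (stable)


def rank_attributes(table: SampleTable) -> CorrelationRanking:
    """Correlate every condition attribute with the target and sort by |rho|.

    Zero-variance attributes get rho = 0 with a warning; a zero-variance
    target is an error.
    """
    if population_std(table.target) == 0.0:
        raise ValueError("rank_attributes: target has zero variance")
    rho = np.empty(table.d)
    for j in range(table.d):
        col = table.values[:, j]
        if population_std(col) == 0.0:
            logger.warning(
                "rank_attributes: attribute %r is constant; assigning rho = 0",
                table.attribute_names[j],
            )
            rho[j] = 0.0
        else:
            rho[j] = pearson_r(col, table.target)
    order = np.argsort(-np.abs(rho), kind="stable")
    return CorrelationRanking(coefficients=rho, order=order)


def removal_order(ranking: CorrelationRanking, remove_largest_first: bool = False) -> list[int]:
    """Sequence in which attributes are deleted during the sweep."""
    order = list(ranking.order)
    return order if remove_largest_first else order[::-1]


@dataclass
class SweepResult:
    """Outcome of the ranked-removal sweep over nested attribute subsets."""

    per_size_scores: dict[int, float]
    best_subset: tuple[int, ...]
    best_size: int
    per_size_subsets: dict[int, tuple[int, ...]] = field(default_factory=dict)
    per_size_best_k: dict[int, int] = field(default_factory=dict)


def sweep_select(
    table: SampleTable,
    ranking: CorrelationRanking | None = None,
    regressor: KNNConfig | MLPConfig = KNNConfig(),
    evaluation: EvalConfig = EvalConfig(),
    remove_largest_first: bool = False,
) -> SweepResult:
    """Score the regressor at every nested subset size d, d-1, ..., 1.

    Each size's score is the pooled cross-validated RMSE (for kNN, minimised
    over the k grid); the returned ``best_size`` attains the lowest score,
    with ties resolved toward fewer attributes.
    """
    ranking = ranking or rank_attributes(table)
    order = removal_order(ranking, remove_largest_first)
    d = table.d
    subset = list(range(d))
    per_size_scores: dict[int, float] = {}
    per_size_subsets: dict[int, tuple[int, ...]] = {}
    per_size_best_k: dict[int, int] = {}
    for step, size in enumerate(range(d, 0, -1)):
        sub = table.subset_attributes(subset)
        if isinstance(regressor, KNNConfig):
            scores = knn_cv_rmse_grid(
                sub, regressor.k_grid, evaluation, normalize=regressor.normalize
            )
            best_j = int(np.argmin(scores))
            per_size_scores[size] = float(scores[best_j])
            per_size_best_k[size] = regressor.k_grid[best_j]
        else:
            per_size_scores[size] = mlp_cv_rmse(sub, regressor, evaluation)
        per_size_subsets[size] = tuple(subset)
        if size > 1:
            subset = [a for a in subset if a != order[step]]
    # ties resolve toward the smaller subset: iterate sizes ascending
    best_size = min(sorted(per_size_scores), key=lambda s: per_size_scores[s])
    return SweepResult(
        per_size_scores=per_size_scores,
        best_subset=per_size_subsets[best_size],
        best_size=best_size,
        per_size_subsets=per_size_subsets,
        per_size_best_k=per_size_best_k,
    )
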