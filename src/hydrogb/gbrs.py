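"""Granular-ball rough set: approximations, positive region, forward selection.

With the ball partition playing the role of the indiscernibility relation,
classical rough-set notions carry over directly: the lower approximation of a
decision concept is the union of balls wholly inside it, the upper
approximation the union of balls intersecting it, and the positive region
(at strict purity) the union of lower approximations over all concepts — which
is exactly the partition's coverage.

Attribute selection is a single greedy forward pass: try each condition
attribute in order, regenerate the partition with it added, and retain it iff
the covered sample count strictly increases.  Rejected attributes are not
retried.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import DiscretizedTarget, SampleTable
from .granular_ball import BallPartition, coverage, generate_partition

__all__ = [
    "GBRSParams",
    "Approximation",
    "TraceEntry",
    "ReductResult",
    "approximate",
    "positive_region_size",
    "forward_select",
    "reduct_to_json",
    "format_selection_report",
]


@dataclass(frozen=True)
class GBRSParams:
    """Knobs of the ball-generation step used throughout the reduction.

    purity_threshold
        Minimum ball purity to stop splitting; 1.0 is the strict positive
        region and the default.
    min_size
        Balls at or below this size are never split (default 1: splitting may
        proceed all the way to singletons; the sample tables here are small).
    seed
        Carried through for interface uniformity; generation is deterministic.
    """

    purity_threshold: float = 1.0
    min_size: int = 1
    seed: int = 0


@dataclass
class Approximation:
    """Lower/upper approximation of one decision concept under subset ``B``."""

    lower: np.ndarray
    upper: np.ndarray
    concept: int
    attribute_subset: tuple[int, ...]


@dataclass
class TraceEntry:
    """One step of the forward-selection loop."""

    attribute: int
    coverage_before: int
    coverage_after: int
    retained: bool


@dataclass
class ReductResult:
    """Selected attribute subset plus the coverage trajectory of the loop."""

    selected: list[int]
    coverage_trace: list[TraceEntry] = field(default_factory=list)
    final_coverage: int = 0


def approximate(
    partition: BallPartition, labels: DiscretizedTarget, concept: int
) -> Approximation:
    """Lower/upper approximation of the sample set carrying class ``concept``.

    Lower = union of balls whose members all carry the concept label;
    upper = union of balls containing at least one such member.
    """
    y = labels.labels
    if concept not in y:
        raise ValueError(f"unknown class code {concept}")
    lower_parts: list[np.ndarray] = []
    upper_parts: list[np.ndarray] = []
    for ball in partition.balls:
        inside = y[ball.member_indices] == concept
        if inside.all():
            lower_parts.append(ball.member_indices)
        if inside.any():
            upper_parts.append(ball.member_indices)
    lower = np.sort(np.concatenate(lower_parts)) if lower_parts else np.empty(0, dtype=int)
    upper = np.sort(np.concatenate(upper_parts)) if upper_parts else np.empty(0, dtype=int)
    return Approximation(
        lower=lower, upper=upper, concept=int(concept), attribute_subset=partition.attribute_subset
    )


def positive_region_size(
    table: SampleTable,
    labels: DiscretizedTarget,
    B: Sequence[int],
    params: GBRSParams | None = None,
    count_singletons: bool = True,
) -> int:
    """Size of the positive region of the decision under attribute subset ``B``.

    At purity threshold 1.0 this equals both the partition coverage and the
    summed sizes of the per-class lower approximations.
    """
    params = params or GBRSParams()
    partition = generate_partition(
        table,
        labels,
        B,
        purity_threshold=params.purity_threshold,
        min_size=params.min_size,
        seed=params.seed,
    )
    return coverage(partition, min_ball_size=1 if count_singletons else 2)


def forward_select(
    table: SampleTable,
    labels: DiscretizedTarget,
    order: Sequence[int] | None = None,
    params: GBRSParams | None = None,
    count_singletons: bool = False,
) -> ReductResult:
    """Greedy forward attribute selection driven by granular-ball coverage.

    Attributes are tried in ``order`` (default: column order).  Each candidate
    is tentatively added, the partition regenerated, and the candidate kept
    iff coverage strictly increases; ties discard it.  With
    ``count_singletons=False`` (the default guard) pure singleton balls do not
    count toward coverage, which prevents spurious saturation on noisy tables
    where every singleton is trivially pure.
    """
    params = params or GBRSParams()
    if order is None:
        order = range(table.d)
    min_ball = 1 if count_singletons else 2
    selected: list[int] = []
    trace: list[TraceEntry] = []
    best = 0
    for a in order:
        candidate = selected + [int(a)]
        partition = generate_partition(
            table,
            labels,
            candidate,
            purity_threshold=params.purity_threshold,
            min_size=params.min_size,
            seed=params.seed,
        )
        cov = coverage(partition, min_ball_size=min_ball)
        retained = cov > best
        trace.append(TraceEntry(int(a), best, cov, retained))
        if retained:
            selected = candidate
            best = cov
    return ReductResult(selected=selected, coverage_trace=trace, final_coverage=best)


def reduct_to_json(result: ReductResult, path: str | Path | None = None) -> str:
    payload = {
        "selected": result.selected,
        "final_coverage": result.final_coverage,
        "trace": [
            {
                "attribute": t.attribute,
                "coverage_before": t.coverage_before,
                "coverage_after": t.coverage_after,
                "retained": t.retained,
            }
            for t in result.coverage_trace
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def format_selection_report(result: ReductResult, attribute_names: Sequence[str]) -> str:
    """Plain-text selection table; attribute positions are printed 1-based."""
    lines = [f"{'pos':>4} {'attribute':<20} {'retained':<9} {'coverage':>8}"]
    for t in result.coverage_trace:
        lines.append(
            f"{t.attribute + 1:>4} {attribute_names[t.attribute]:<20} "
            f"{'yes' if t.retained else 'no':<9} {t.coverage_after:>8}"
        )
    lines.append(
        f"selected ({len(result.selected)}): "
        + ", ".join(str(a + 1) for a in result.selected)
        + f"  final coverage {result.final_coverage}"
    )
    return "\n".join(lines)
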