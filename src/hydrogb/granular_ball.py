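"""Purity-driven granular-ball partitions.

A granular ball summarises a group of samples by its center ``c`` (the mean
of its members) and radius ``r`` (the mean Euclidean distance of members to
the center).  Given class labels for the samples, a ball's *purity* is the
fraction of members carrying the majority label.  The partition generator
starts from one ball covering all samples under a chosen attribute subset
``B`` and recursively splits impure balls with a deterministic two-center
(2-means) step seeded by the farthest pair of members, until every ball is
either pure enough or unsplittable (all member coordinates identical).

The resulting set of balls is the equivalence-class partition of the sample
universe induced by ``B``; its *coverage* — the number of samples lying in
balls whose purity reaches the threshold — is the quantity the rough-set
attribute-selection loop maximises.

Membership is by construction: every sample belongs to exactly one ball,
the one whose splitting lineage it followed.  (A purely geometric membership
test against ``r`` would leave samples outside all balls, since the radius
is a *mean* member distance.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import DiscretizedTarget, SampleTable

__all__ = [
    "GranularBall",
    "BallPartition",
    "center_radius",
    "make_ball",
    "split_ball",
    "generate_partition",
    "coverage",
    "partition_to_json",
]

_MAX_LLOYD_ITER = 100


@dataclass
class GranularBall:
    """One granule: center, radius, member sample indices, purity."""

    center: np.ndarray
    radius: float
    member_indices: np.ndarray
    majority_label: int
    purity: float
    unsplittable: bool = False

    @property
    def size(self) -> int:
        return self.member_indices.size


@dataclass
class BallPartition:
    """The ball partition induced by an attribute subset.

    ``coverage`` is the literal count of samples lying in balls whose purity
    meets ``purity_threshold`` (singletons included); use :func:`coverage`
    with ``min_ball_size=2`` for the singleton-guarded count.
    """

    balls: list[GranularBall]
    attribute_subset: tuple[int, ...]
    purity_threshold: float
    coverage: int = field(init=False)

    def __post_init__(self) -> None:
        self.coverage = coverage(self)


def center_radius(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean center and mean member-to-center Euclidean distance.

    A singleton has radius 0.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("center_radius: empty point set")
    c = pts.mean(axis=0)
    r = float(np.linalg.norm(pts - c, axis=1).mean())
    return c, r


def make_ball(
    X: np.ndarray, labels: np.ndarray, member_indices: np.ndarray, unsplittable: bool = False
) -> GranularBall:
    """Build a ball over ``member_indices`` of the coordinate matrix ``X``."""
    members = np.sort(np.asarray(member_indices, dtype=int))
    c, r = center_radius(X[members])
    lab = labels[members]
    counts = np.bincount(lab)
    majority = int(np.argmax(counts))  # ties -> smallest class code
    purity = float(counts[majority]) / members.size
    return GranularBall(
        center=c,
        radius=r,
        member_indices=members,
        majority_label=majority,
        purity=purity,
        unsplittable=unsplittable,
    )


def _two_means(pts: np.ndarray) -> np.ndarray | None:
    """Deterministic 2-means assignment of ``pts``; ``None`` if degenerate.

    Centers start at the farthest pair of points (first such pair in row-major
    order on ties); Lloyd iterations run until the assignment is stable.
    Distance ties assign to the first center.
    """
    m = pts.shape[0]
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if d2.max() == 0.0:
        return None  # all coordinates identical
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = np.stack([pts[i], pts[j]])
    assign = np.zeros(m, dtype=int)
    for _ in range(_MAX_LLOYD_ITER):
        d0 = np.linalg.norm(pts - centers[0], axis=1)
        d1 = np.linalg.norm(pts - centers[1], axis=1)
        new_assign = (d1 < d0).astype(int)
        if new_assign.sum() in (0, m):
            break  # would empty a cluster; keep previous stable assignment
        if np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
        centers = np.stack([pts[assign == 0].mean(axis=0), pts[assign == 1].mean(axis=0)])
    if assign.sum() in (0, m):
        # fall back to the farthest-pair seeding itself
        d0 = np.linalg.norm(pts - pts[i], axis=1)
        d1 = np.linalg.norm(pts - pts[j], axis=1)
        assign = (d1 < d0).astype(int)
        if assign.sum() in (0, m):
            return None
    return assign


def split_ball(
    ball: GranularBall, X: np.ndarray, labels: np.ndarray
) -> list[GranularBall]:
    """Split a ball into two children by deterministic 2-means.

    Returns the ball unchanged (flagged unsplittable) when all member
    coordinates coincide.
    """
    if ball.size < 2:
        raise ValueError("split_ball: ball has fewer than 2 members")
    members = ball.member_indices
    assign = _two_means(X[members])
    if assign is None:
        ball.unsplittable = True
        return [ball]
    left = members[assign == 0]
    right = members[assign == 1]
    return [make_ball(X, labels, left), make_ball(X, labels, right)]


def generate_partition(
    table: SampleTable,
    labels: DiscretizedTarget,
    B: Sequence[int],
    purity_threshold: float = 1.0,
    min_size: int = 1,
    seed: int = 0,
) -> BallPartition:
    """Grow the granular-ball partition of the table under attribute subset ``B``.

    Starting from one ball over all samples, any ball with purity below the
    threshold and more than ``min_size`` members is split; the loop stops when
    no ball is splittable.  The procedure is fully deterministic (the 2-means
    seeding is the farthest member pair); ``seed`` is accepted for interface
    uniformity with the rest of the toolkit.
    """
    B = tuple(int(b) for b in B)
    if len(B) == 0:
        raise ValueError("generate_partition: empty attribute subset")
    if not 0.0 < purity_threshold <= 1.0:
        raise ValueError("purity_threshold must be in (0, 1]")
    del seed  # deterministic by construction
    X = table.values[:, list(B)]
    y = labels.labels
    queue = [make_ball(X, y, np.arange(table.n))]
    finished: list[GranularBall] = []
    while queue:
        ball = queue.pop()
        if ball.purity >= purity_threshold or ball.size <= min_size or ball.unsplittable:
            finished.append(ball)
            continue
        children = split_ball(ball, X, y)
        if len(children) == 1:
            finished.append(children[0])
        else:
            queue.extend(children)
    finished.sort(key=lambda b: int(b.member_indices[0]))
    return BallPartition(balls=finished, attribute_subset=B, purity_threshold=purity_threshold)


def coverage(partition: BallPartition, min_ball_size: int = 1) -> int:
    """Number of samples in balls whose purity meets the partition threshold.

    ``min_ball_size=2`` excludes singleton balls, which are trivially pure and
    would otherwise saturate the count on noisy tables.
    """
    return int(
        sum(
            b.size
            for b in partition.balls
            if b.purity >= partition.purity_threshold and b.size >= min_ball_size
        )
    )


def partition_to_json(partition: BallPartition, path: str | Path | None = None) -> str:
    """Serialise a partition (centers, radii, members, purity) for inspection."""
    payload = {
        "attribute_subset": list(partition.attribute_subset),
        "purity_threshold": partition.purity_threshold,
        "coverage": partition.coverage,
        "balls": [
            {
                "center": b.center.tolist(),
                "radius": b.radius,
                "members": b.member_indices.tolist(),
                "majority_label": b.majority_label,
                "purity": b.purity,
                "unsplittable": b.unsplittable,
            }
            for b in partition.balls
        ],
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
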