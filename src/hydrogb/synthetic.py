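"""Synthetic monitoring tables with planted structure.

Real algal-monitoring tables of the kind this toolkit targets are small
(roughly five years of monthly sampling followed by quarterly sampling,
~60–70 rows), wide-ish (~13 hydrological/chemical condition attributes), and
carry non-negative, strongly right-skewed chlorophyll targets on scales of
hundreds to tens of thousands of units.  Only a handful of attributes carry
signal; several others are near-duplicates of those, and the rest are noise.

The generator emulates exactly that anatomy with known ground truth:

* informative attributes follow a seasonal sinusoid plus AR(1) noise,
* redundant attributes are affine copies of informative ones plus jitter,
* noise attributes are i.i.d. standard normal,
* the target is a (by default exponential) function of a linear index of the
  informative attributes and the seasonal term, scaled, perturbed with
  Gaussian noise and clipped at zero — producing bloom-like spikes.

Everything is deterministic for a fixed seed, so every stage of the toolkit
is testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .data_model import SampleTable

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate",
    "planted_truth",
    "recovery_score",
    "paper_like_spec",
]

EffectFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic monitoring table.

    noise_sd is the standard deviation of the additive target noise as a
    fraction of ``target_scale``; jitter_sd is the absolute jitter added to
    redundant copies (informative attributes have spread ~1).
    """

    n: int = 68
    d_informative: int = 3
    d_redundant: int = 4
    d_noise: int = 6
    effect: str | EffectFn = "exp"
    noise_sd: float = 0.2
    target_scale: float = 2000.0
    jitter_sd: float = 0.05
    seasonal_period: int = 12
    sparse_tail: int = 8
    sparse_step: int = 3
    seed: int = 0

    @property
    def d(self) -> int:
        return self.d_informative + self.d_redundant + self.d_noise

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("at least one attribute is required")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.d_informative < 0 or self.d_redundant < 0 or self.d_noise < 0:
            raise ValueError("attribute counts must be non-negative")
        if self.d_redundant > 0 and self.d_informative == 0:
            raise ValueError("redundant attributes need an informative source")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class PlantedTruth:
    informative: tuple[int, ...]
    redundant: tuple[int, ...]
    noise: tuple[int, ...]


def _time_index(spec: SyntheticSpec) -> np.ndarray:
    """Monthly cadence switching to sparse (quarterly-like) for the tail."""
    n_dense = max(spec.n - spec.sparse_tail, 0)
    dense = np.arange(n_dense, dtype=float)
    start = dense[-1] + spec.sparse_step if n_dense else 0.0
    sparse = start + spec.sparse_step * np.arange(spec.n - n_dense, dtype=float)
    return np.concatenate([dense, sparse])


def _effect(spec: SyntheticSpec, X_inf: np.ndarray, season: np.ndarray, eta: np.ndarray) -> np.ndarray:
    if callable(spec.effect):
        return spec.effect(X_inf, season)
    z = (eta - eta.mean()) / (eta.std() or 1.0)
    if spec.effect == "exp":
        return np.exp(0.9 * z)
    if spec.effect == "linear":
        return z - z.min()
    if spec.effect == "threshold":
        return np.where(z > 0.5, 1.5 + z, 0.1)
    raise ValueError(f"unknown effect {spec.effect!r}")


def generate(spec: SyntheticSpec) -> SampleTable:
    """Draw one table; identical output for identical specs."""
    rng = np.random.default_rng(spec.seed)
    t = _time_index(spec)
    season = np.sin(2.0 * np.pi * t / spec.seasonal_period)

    cols: list[np.ndarray] = []
    names: list[str] = []
    # informative: seasonal signal + AR(1) irregularity
    X_inf = np.empty((spec.n, spec.d_informative))
    for j in range(spec.d_informative):
        amp = rng.uniform(0.5, 1.0)
        ar = np.empty(spec.n)
        e = rng.normal(0.0, 0.6, size=spec.n)
        ar[0] = e[0]
        for i in range(1, spec.n):
            ar[i] = 0.6 * ar[i - 1] + e[i]
        X_inf[:, j] = amp * season + ar
        cols.append(X_inf[:, j])
        names.append(f"inf_{j + 1}")
    # redundant: affine copies of informative sources + jitter
    for j in range(spec.d_redundant):
        src = X_inf[:, j % spec.d_informative]
        alpha = rng.uniform(0.8, 1.2)
        beta = rng.normal(0.0, 0.2)
        cols.append(alpha * src + beta + rng.normal(0.0, spec.jitter_sd, size=spec.n))
        names.append(f"red_{j + 1}")
    # pure noise
    for j in range(spec.d_noise):
        cols.append(rng.normal(0.0, 1.0, size=spec.n))
        names.append(f"noise_{j + 1}")

    if spec.d_informative:
        w = rng.uniform(0.6, 1.2, size=spec.d_informative)
        eta = X_inf @ w + 0.5 * season
    else:
        eta = 0.5 * season
    raw = _effect(spec, X_inf, season, eta)
    target = spec.target_scale * raw + rng.normal(
        0.0, spec.noise_sd * spec.target_scale, size=spec.n
    )
    target = np.clip(target, 0.0, None)
    return SampleTable(
        values=np.column_stack(cols),
        target=target,
        attribute_names=names,
        sample_ids=[f"s{i + 1:03d}" for i in range(spec.n)],
    )


def planted_truth(spec: SyntheticSpec) -> PlantedTruth:
    """Index sets of the informative / redundant / noise attribute blocks."""
    a = spec.d_informative
    b = a + spec.d_redundant
    return PlantedTruth(
        informative=tuple(range(a)),
        redundant=tuple(range(a, b)),
        noise=tuple(range(b, spec.d)),
    )


def recovery_score(selected: Sequence[int], truth: PlantedTruth) -> float:
    """Fraction of selected attributes that carry signal (informative or redundant)."""
    selected = list(selected)
    if not selected:
        return 0.0
    good = set(truth.informative) | set(truth.redundant)
    return sum(1 for a in selected if a in good) / len(selected)


def paper_like_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The default study-sized preset: n=68, 13 attributes (3+4+6)."""
    return replace(SyntheticSpec(seed=seed), **overrides)
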