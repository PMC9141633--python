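"""Permutation-null significance testing and scenario benchmarking.

For a region pair and a connectivity measure, the null distribution is
built by independently shuffling every voxel's time series (in both
regions) and recomputing the measure; a connection is significant when its
observed value strictly exceeds the 95th percentile of that null. The
signed distance between the observed value and the threshold is the
*performance* of the measure on that pair — positive means detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measures import RegionActivity, compute_measure
from .simulate import ScenarioSpec, SimulatedPair, shuffle_voxels, simulate_pair

__all__ = [
    "NullDistribution",
    "EdgeVerdict",
    "build_null",
    "percentile95",
    "performance",
    "scenario_performance",
    "DEFAULT_N_PERM",
]

DEFAULT_N_PERM = 100


@dataclass(frozen=True)
class NullDistribution:
    """Permutation FC values for one edge under one measure."""

    values: np.ndarray
    measure_tag: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 20:
            raise ValueError(f"need a 1-D null of >= 20 permutations, got shape {arr.shape}")
        object.__setattr__(self, "values", arr)

    @property
    def n_perm(self) -> int:
        return self.values.size

    def percentile(self, q: float) -> float:
        # linear interpolation between order statistics; fixed convention so
        # the n_perm=100 threshold is reproducible across numpy versions
        return float(np.percentile(self.values, q, method="linear"))


@dataclass(frozen=True)
class EdgeVerdict:
    """Observed value vs. its permutation threshold for one edge."""

    fc_value: float
    threshold95: float

    @property
    def performance(self) -> float:
        return self.fc_value - self.threshold95

    @property
    def significant(self) -> bool:
        # strict inequality: a value exactly at the threshold is not significant
        return self.fc_value > self.threshold95


def build_null(
    x: RegionActivity,
    y: RegionActivity,
    measure: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    **measure_kwargs,
) -> NullDistribution:
    """Permutation null of a measure on a region pair; deterministic given seed."""
    if n_perm < 20:
        raise ValueError(f"n_perm must be >= 20, got {n_perm}")
    rng = np.random.default_rng(seed)
    values = np.empty(n_perm)
    for i in range(n_perm):
        try:
            values[i] = compute_measure(
                measure, shuffle_voxels(x, rng), shuffle_voxels(y, rng), **measure_kwargs
            )
        except Exception as exc:
            raise RuntimeError(f"measure {measure!r} failed at permutation {i}: {exc}") from exc
    return NullDistribution(values=values, measure_tag=measure)


def percentile95(null: NullDistribution) -> float:
    """Empirical 95th percentile of the null (linear interpolation)."""
    return null.percentile(95.0)


def performance(fc_value: float, null: NullDistribution) -> EdgeVerdict:
    """Signed distance of an observed FC value from the null's 95th percentile."""
    return EdgeVerdict(fc_value=float(fc_value), threshold95=percentile95(null))


def scenario_performance(
    spec: ScenarioSpec,
    measure: str,
    reps: int = 20,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and SD of a measure's performance over scenario repetitions.

    Each repetition simulates a fresh pair (seed derived from ``seed``),
    builds its permutation null, and records observed value minus
    threshold. The returned (mean, sd) pair is the bar and error bar of the
    benchmark.
    """
    perfs = repeated_performance(spec, measure, reps=reps, n_perm=n_perm, seed=seed)
    return float(np.mean(perfs)), float(np.std(perfs, ddof=1))


def repeated_performance(
    spec: ScenarioSpec,
    measure: str,
    reps: int = 20,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> np.ndarray:
    """Per-repetition performance values underlying :func:`scenario_performance`."""
    if reps < 1:
        raise ValueError("reps must be positive")
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=(reps, 2))
    perfs = np.empty(reps)
    for i, (sim_seed, null_seed) in enumerate(rep_seeds):
        pair = simulate_pair(spec.with_seed(int(sim_seed)))
        observed = compute_measure(measure, pair.region_x, pair.region_y)
        null = build_null(
            pair.region_x, pair.region_y, measure, n_perm=n_perm, seed=int(null_seed)
        )
        perfs[i] = performance(observed, null).performance
    return perfs
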