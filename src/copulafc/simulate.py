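"""Two-region interaction simulator.

Generates pairs of voxel-resolved regions whose dependence is controlled by
a mapping Y_t = f(X_t @ T) + w_t: region X is drawn i.i.d. over time from a
multivariate normal whose covariance sets the within-region homogeneity, T
maps X's voxels to Y's, f is the identity (linear scenario) or an
elementwise square (nonlinear scenario), and w_t is additive Gaussian
measurement noise. A structural-noise scenario adds one shared noise series
to every voxel of Y, mimicking global artifacts such as head motion.

Three covariance regimes set the homogeneity of X:

- ``homogeneous``: (1-c)*I + c*J — all voxels highly positively correlated;
- ``independent``: I — voxels uncorrelated;
- ``mixed``: (1-c)*I + c*v v^T with v = +1 on the first half, -1 on the
  second — two anticorrelated voxel blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .measures import RegionActivity

__all__ = [
    "CovarianceRegime",
    "ScenarioSpec",
    "SimulatedPair",
    "make_covariance",
    "simulate_pair",
    "null_pair",
    "shuffle_voxels",
    "SCENARIOS",
    "REGIMES",
]

SCENARIOS = ("linear", "nonlinear_square", "multivariate", "structural_noise")
REGIMES = ("homogeneous", "independent", "mixed")


@dataclass(frozen=True)
class CovarianceRegime:
    """Homogeneity regime of the source region's voxel covariance."""

    kind: str
    strength: float = 0.9
    size: int = 100

    def __post_init__(self) -> None:
        if self.kind not in REGIMES:
            raise ValueError(f"regime kind must be one of {REGIMES}, got {self.kind!r}")
        if not 0.0 < self.strength < 1.0:
            raise ValueError(f"strength must lie in (0, 1), got {self.strength}")
        if self.size < 1:
            raise ValueError("size must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one simulation condition.

    Defaults follow the benchmark design: regions of 100 and 150 voxels
    observed over 500 timepoints. Noise magnitudes are configurable;
    ``structural_noise_sd`` only matters for the structural_noise scenario.
    ``measurement_noise_on_x`` adds the measurement noise to the source
    region as well as the target (set False to restrict it to Y).
    """

    scenario: str = "linear"
    regime: str = "homogeneous"
    n_x: int = 100
    n_y: int = 150
    n_timepoints: int = 500
    strength: float = 0.9
    mapping_noise_sd: float = 0.1
    measurement_noise_sd: float = 0.5
    # Shared-noise sd large enough that the average-series correlation falls
    # below the n=500 permutation threshold (~1.96/sqrt(n)); see docs/methods.md.
    structural_noise_sd: float = 12.0
    measurement_noise_on_x: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        for name in ("n_x", "n_y", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("mapping_noise_sd", "measurement_noise_sd", "structural_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def covariance_regime(self) -> CovarianceRegime:
        return CovarianceRegime(kind=self.regime, strength=self.strength, size=self.n_x)

    def with_seed(self, seed: int) -> "ScenarioSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedPair:
    """A simulated (X, Y) region pair plus the spec that produced it."""

    region_x: RegionActivity
    region_y: RegionActivity
    spec: ScenarioSpec


def make_covariance(regime: CovarianceRegime) -> np.ndarray:
    """Build the regime's voxel covariance matrix and verify it is PD."""
    n, c = regime.size, regime.strength
    if regime.kind == "independent":
        cov = np.eye(n)
    elif regime.kind == "homogeneous":
        cov = (1.0 - c) * np.eye(n) + c * np.ones((n, n))
    else:  # mixed: two anticorrelated halves
        v = np.ones(n)
        v[(n + 1) // 2 :] = -1.0
        cov = (1.0 - c) * np.eye(n) + c * np.outer(v, v)
    np.linalg.cholesky(cov)  # raises if not PD
    return cov


def _mapping_matrix(spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Voxel-to-voxel mapping T of shape (n_x, n_y)."""
    if spec.scenario == "multivariate":
        # Dense Gaussian mixing; 1/sqrt(n_x) scale keeps Y variance O(1).
        # The empirical grand mean is removed so the zero-mean ensemble holds
        # exactly in sample: otherwise the grand mean of T couples the two
        # regions' voxel-average series, and the scenario would carry a
        # univariate (average-to-average) component alongside the
        # multivariate one it is meant to isolate.
        t = rng.normal(0.0, 1.0 / np.sqrt(spec.n_x), size=(spec.n_x, spec.n_y))
        return t - t.mean()
    t = np.zeros((spec.n_x, spec.n_y))
    k = min(spec.n_x, spec.n_y)
    t[:k, :k] = np.eye(k)[: spec.n_x, :k]
    if spec.n_y > spec.n_x:
        t[:, spec.n_x :] = rng.normal(
            0.0, spec.mapping_noise_sd, size=(spec.n_x, spec.n_y - spec.n_x)
        )
    return t


def simulate_pair(spec: ScenarioSpec) -> SimulatedPair:
    """Generate one (X, Y) pair under the scenario; deterministic given seed.

    X columns (timepoints) are i.i.d. draws from N(0, Sigma_regime). Y is
    f(X^T @ T)^T plus noise, where f is the identity except in the
    nonlinear_square scenario (elementwise square). Measurement noise is
    added to both regions; the structural_noise scenario additionally adds a
    single shared noise series to every voxel of Y.
    """
    rng = np.random.default_rng(spec.seed)
    cov = make_covariance(spec.covariance_regime())
    # voxels x timepoints; each column one multivariate-normal draw
    x = rng.multivariate_normal(
        np.zeros(spec.n_x), cov, size=spec.n_timepoints, method="cholesky"
    ).T

    t_map = _mapping_matrix(spec, rng)
    y = (x.T @ t_map).T  # n_y x timepoints
    if spec.scenario == "nonlinear_square":
        y = y**2

    if spec.measurement_noise_sd > 0:
        if spec.measurement_noise_on_x:
            x = x + rng.normal(0.0, spec.measurement_noise_sd, size=x.shape)
        y = y + rng.normal(0.0, spec.measurement_noise_sd, size=y.shape)
    if spec.scenario == "structural_noise" and spec.structural_noise_sd > 0:
        shared = rng.normal(0.0, spec.structural_noise_sd, size=spec.n_timepoints)
        y = y + shared[np.newaxis, :]

    return SimulatedPair(
        region_x=RegionActivity(x, region_id="X"),
        region_y=RegionActivity(y, region_id="Y"),
        spec=spec,
    )


def shuffle_voxels(region: RegionActivity, rng: np.random.Generator) -> RegionActivity:
    """Independently permute each voxel's time series over time.

    Destroys all temporal alignment (cross-region and cross-voxel) while
    leaving each voxel's marginal value distribution untouched.
    """
    data = rng.permuted(region.data, axis=1)
    return RegionActivity(data, region_id=region.region_id)


def null_pair(pair: SimulatedPair, seed: int) -> SimulatedPair:
    """Null version of a pair: every voxel of both regions shuffled in time."""
    rng = np.random.default_rng(seed)
    return SimulatedPair(
        region_x=shuffle_voxels(pair.region_x, rng),
        region_y=shuffle_voxels(pair.region_y, rng),
        spec=pair.spec,
    )
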