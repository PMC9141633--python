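"""Synthetic multi-subject cohort with a shared network backbone.

Emulates the structure of a parcellated resting-state cohort: regions are
grouped into functional networks (seven by default), every region mixes a
latent signal shared by its network with a weaker global signal, and the
latents are common to all subjects — so within-network connectivity is
stronger than between-network connectivity and subjects share a connectivity
backbone. Per-subject noise controls how similar subjects are; an optional
strictly monotone per-region distortion makes regional amplitudes
non-Gaussian in a region-specific way, which degrades correlation-based
measures but not rank-based ones.

This generator emulates network structure only: it has no haemodynamics, no
temporal autocorrelation, and no spatial voxel layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .measures import RegionActivity
from .network import NetworkAssignment

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "DEFAULT_NETWORKS"]

DEFAULT_NETWORKS = ("Vis", "SomMot", "DorsAttn", "SalVentAttn", "Limbic", "Cont", "Default")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    ``within_strength`` must exceed ``between_strength`` so the generated
    networks show the high within / low between interaction structure of
    resting-state communities. ``subject_noise_sd`` is region-level noise
    independent across subjects; ``voxel_noise_sd`` is independent noise per
    voxel. ``nonlinear`` applies a random strictly monotone distortion per
    region (shared across subjects, as regional response profiles are a
    property of the region, not the scan).
    """

    n_subjects: int = 8
    regions_per_network: int = 4
    network_labels: tuple[str, ...] = DEFAULT_NETWORKS
    voxels_range: tuple[int, int] = (8, 12)
    n_timepoints: int = 150
    within_strength: float = 1.0
    between_strength: float = 0.3
    subject_noise_sd: float = 0.6
    voxel_noise_sd: float = 0.6
    # Per-subject voxel signal weights ~ N(gain_mean, gain_sd): with the
    # defaults a region holds a subject-specific mix of positively and
    # negatively weighted voxels, so the voxel average is a good summary for
    # some subjects and a poor one for others (inhomogeneous regions), while
    # the multivariate structure keeps the latent signal for everyone.
    voxel_gain_mean: float = 0.5
    voxel_gain_sd: float = 1.0
    nonlinear: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.regions_per_network < 1 or self.n_timepoints < 3:
            raise ValueError("cohort sizes must be positive (and >= 3 timepoints)")
        if self.voxels_range[0] < 1 or self.voxels_range[1] < self.voxels_range[0]:
            raise ValueError(f"invalid voxels_range {self.voxels_range}")
        if not self.within_strength > self.between_strength:
            raise ValueError(
                "within_strength must exceed between_strength "
                f"({self.within_strength} vs {self.between_strength})"
            )

    @property
    def n_regions(self) -> int:
        return self.regions_per_network * len(self.network_labels)


@dataclass(frozen=True)
class Cohort:
    """Per-subject region lists plus the region -> network assignment."""

    subjects: tuple[tuple[RegionActivity, ...], ...]
    assignment: NetworkAssignment
    spec: CohortSpec

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


def _monotone_distortion(rng: np.random.Generator):
    """A random strictly increasing map: x -> x + a*x^3 or a signed power."""
    kind = rng.integers(0, 2)
    if kind == 0:
        a = float(rng.uniform(0.1, 0.6))
        return lambda x, a=a: x + a * x**3
    p = float(rng.uniform(1.5, 3.0))
    return lambda x, p=p: np.sign(x) * np.abs(x) ** p


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the cohort; deterministic given ``spec.seed``.

    Latent network signals, the global signal, region voxel counts and any
    nonlinear distortions are drawn once at the cohort level; each subject
    then adds independent region- and voxel-level noise.
    """
    root = np.random.default_rng(spec.seed)
    n_net = len(spec.network_labels)
    t = spec.n_timepoints

    latents = root.normal(size=(n_net, t))  # shared network backbone
    global_sig = root.normal(size=t)
    voxel_counts = root.integers(
        spec.voxels_range[0], spec.voxels_range[1] + 1, size=spec.n_regions
    )
    distortions = (
        [_monotone_distortion(root) for _ in range(spec.n_regions)]
        if spec.nonlinear
        else [None] * spec.n_regions
    )

    region_ids, labels = [], {}
    for ni, name in enumerate(spec.network_labels):
        for ri in range(spec.regions_per_network):
            rid = f"{name}_{ri}"
            region_ids.append((rid, ni))
            labels[rid] = name

    subject_seeds = root.integers(0, 2**31 - 1, size=spec.n_subjects)
    subjects = []
    for s in range(spec.n_subjects):
        srng = np.random.default_rng(int(subject_seeds[s]))
        regions = []
        for (rid, ni), n_vox, distort in zip(region_ids, voxel_counts, distortions):
            base = (
                spec.within_strength * latents[ni]
                + spec.between_strength * global_sig
                + spec.subject_noise_sd * srng.normal(size=t)
            )
            gains = spec.voxel_gain_mean + spec.voxel_gain_sd * srng.normal(size=n_vox)
            voxels = gains[:, np.newaxis] * base + spec.voxel_noise_sd * srng.normal(
                size=(n_vox, t)
            )
            if distort is not None:
                voxels = distort(voxels)
            regions.append(RegionActivity(voxels, region_id=rid))
        subjects.append(tuple(regions))

    return Cohort(
        subjects=tuple(subjects),
        assignment=NetworkAssignment(labels=labels),
        spec=spec,
    )
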