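"""Region-pair functional-connectivity measures.

Four estimators of the statistical dependence between two brain regions,
each region given as a voxels x timepoints matrix:

- ``pcor``   : |Pearson r| between the two voxel-average time series.
- ``svd_fc`` : |Pearson r| between the first temporal singular vectors of the
  voxel-centered matrices (robust when a region is inhomogeneous).
- ``uv_mi``  : Gaussian-copula MI between the average series, rescaled to a
  correlation-scale magnitude in [0, 1).
- ``mv_mi``  : Gaussian-copula MI between the top-5 PCA component score
  series of each region — multivariate and nonlinear, so it sees dependence
  that averaging or linearity would hide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gcmi import MultivariateSample, gcmi, rescale_mi

__all__ = [
    "RegionActivity",
    "RegionSummary",
    "summarize_region",
    "pcor",
    "svd_fc",
    "uv_mi",
    "mv_mi",
    "MEASURES",
    "compute_measure",
]

DEFAULT_N_COMPONENTS = 5


@dataclass(frozen=True)
class RegionActivity:
    """One region's activity: a voxels x timepoints matrix."""

    data: np.ndarray
    region_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise ValueError(f"region data must be 2-D (voxels x timepoints), got ndim={arr.ndim}")
        if arr.shape[0] < 1:
            raise ValueError("region must contain at least one voxel")
        if arr.shape[1] < 3:
            raise ValueError(f"region needs >= 3 timepoints, got {arr.shape[1]}")
        if not np.isfinite(arr).all():
            raise ValueError(f"region {self.region_id!r} contains non-finite values")
        object.__setattr__(self, "data", arr)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RegionSummary:
    """Reduced representation of a region: components x timepoints."""

    series: np.ndarray
    method: str

    @property
    def n_components(self) -> int:
        return self.series.shape[0]


def _center_voxels(data: np.ndarray) -> np.ndarray:
    # per-voxel mean removal over time; BOLD units retained (no scaling)
    return data - data.mean(axis=1, keepdims=True)


def _fix_component_signs(components: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude voxel loading is positive."""
    out = components.copy()
    for i in range(loadings.shape[1]):
        col = loadings[:, i]
        if col[np.argmax(np.abs(col))] < 0:
            out[i] = -out[i]
    return out


def _principal_parts(centered: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k PCA of a centered voxels x timepoints matrix.

    Returns (scores, loadings, singular_values) where scores[i] = s_i * v_i
    (the i-th temporal PC score series) and loadings columns are the voxel
    singular vectors. Works through the Gram matrix of the smaller side,
    which is much cheaper than a full SVD for wide or tall matrices.
    """
    v, t = centered.shape
    if v <= t:
        gram = centered @ centered.T
        eigvals, u = np.linalg.eigh(gram)
        idx = np.argsort(eigvals)[::-1][:k]
        s = np.sqrt(np.clip(eigvals[idx], 0.0, None))
        loadings = u[:, idx]
        scores = loadings.T @ centered  # u_i^T M = s_i v_i^T
    else:
        gram = centered.T @ centered
        eigvals, vv = np.linalg.eigh(gram)
        idx = np.argsort(eigvals)[::-1][:k]
        s = np.sqrt(np.clip(eigvals[idx], 0.0, None))
        vt = vv[:, idx].T
        scores = s[:, np.newaxis] * vt
        with np.errstate(divide="ignore", invalid="ignore"):
            loadings = np.where(s > 0, (centered @ vt.T) / s, 0.0)
    return scores, loadings, s


def summarize_region(
    region: RegionActivity, method: str, n_components: int = DEFAULT_N_COMPONENTS
) -> RegionSummary:
    """Reduce a region's voxel matrix to one or a few time series.

    ``mean`` averages across voxels; ``svd_first`` takes the temporal
    singular vector of the largest singular value of the voxel-centered
    matrix; ``pca_k`` returns the top-``n_components`` temporal PC score
    series ordered by decreasing explained variance. If a region cannot
    support the requested component count (too few voxels or timepoints, or
    rank deficiency) it is reduced with a warning.
    """
    if method not in ("mean", "svd_first", "pca_k"):
        raise ValueError(f"unknown summary method {method!r}")
    data = region.data
    if method == "mean":
        return RegionSummary(series=data.mean(axis=0, keepdims=True), method=method)

    centered = _center_voxels(data)
    if method == "svd_first":
        scores, loadings, s = _principal_parts(centered, 1)
        if s[0] == 0:
            raise ValueError(f"region {region.region_id!r} has no variance over time")
        v1 = _fix_component_signs(scores / s[0], loadings)
        return RegionSummary(series=v1, method=method)

    max_k = min(region.n_voxels, region.n_timepoints - 1)
    if n_components > max_k:
        warnings.warn(
            f"region {region.region_id!r} supports at most {max_k} components; "
            f"reducing from {n_components}",
            stacklevel=2,
        )
        n_components = max_k
    scores, loadings, s = _principal_parts(centered, n_components)
    # drop numerically dead components (rank-deficient regions)
    usable = s > s[0] * 1e-8 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    if not usable.all():
        warnings.warn(
            f"region {region.region_id!r} has rank {int(usable.sum())}; "
            f"returning {int(usable.sum())} of {n_components} components",
            stacklevel=2,
        )
        scores = scores[usable]
        loadings = loadings[:, usable]
    scores = _fix_component_signs(scores, loadings)
    return RegionSummary(series=scores, method="pca_k")


def _abs_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.ravel(a)
    b = np.ravel(b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero-variance summary series; correlation undefined")
    return float(abs(stats.pearsonr(a, b).statistic))


def pcor(x: RegionActivity, y: RegionActivity) -> float:
    """|Pearson correlation| between the two regions' voxel-average series."""
    _check_aligned(x, y)
    return _abs_pearson(
        summarize_region(x, "mean").series, summarize_region(y, "mean").series
    )


def svd_fc(x: RegionActivity, y: RegionActivity) -> float:
    """|Pearson correlation| between first temporal singular vectors.

    The absolute value absorbs the sign indeterminacy of singular vectors.
    """
    _check_aligned(x, y)
    return _abs_pearson(
        summarize_region(x, "svd_first").series, summarize_region(y, "svd_first").series
    )


def uv_mi(x: RegionActivity, y: RegionActivity) -> float:
    """Rescaled Gaussian-copula MI between the voxel-average series, in [0, 1)."""
    _check_aligned(x, y)
    mx = summarize_region(x, "mean").series
    my = summarize_region(y, "mean").series
    return rescale_mi(gcmi(MultivariateSample(mx), MultivariateSample(my)))


def mv_mi(
    x: RegionActivity, y: RegionActivity, n_components: int = DEFAULT_N_COMPONENTS
) -> float:
    """Rescaled Gaussian-copula MI between the regions' PCA score blocks.

    Each region is reduced to its top-``n_components`` principal-component
    score series; the MI of the joint 2*n_components-dimensional copula
    covariance is rescaled to [0, 1). Requires
    n_timepoints > 2*n_components + 1 for a full-rank joint covariance.
    """
    _check_aligned(x, y)
    required = 2 * n_components + 2
    if x.n_timepoints < required:
        raise ValueError(
            f"mv_mi with n_components={n_components} needs >= {required} timepoints, "
            f"got {x.n_timepoints}"
        )
    sx = summarize_region(x, "pca_k", n_components).series
    sy = summarize_region(y, "pca_k", n_components).series
    return rescale_mi(gcmi(MultivariateSample(sx), MultivariateSample(sy)))


def _check_aligned(x: RegionActivity, y: RegionActivity) -> None:
    if x.n_timepoints != y.n_timepoints:
        raise ValueError(
            f"regions must share timepoints: {x.n_timepoints} vs {y.n_timepoints}"
        )


MEASURES = {"pcor": pcor, "svd": svd_fc, "uvmi": uv_mi, "mvmi": mv_mi}


def compute_measure(name: str, x: RegionActivity, y: RegionActivity, **kwargs) -> float:
    """Dispatch a measure by name ('pcor', 'svd', 'uvmi', 'mvmi')."""
    try:
        fn = MEASURES[name]
    except KeyError:
        raise ValueError(f"unknown measure {name!r}; choose from {sorted(MEASURES)}") from None
    return fn(x, y, **kwargs)
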