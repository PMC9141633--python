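"""Gaussian-copula mutual information.

Mutual information between continuous variables equals the negative entropy
of their copula, so it can be estimated independently of the marginals: each
dimension is rank-transformed to a standard-normal marginal, and the joint
dependence is then summarised by the covariance of the transformed data.
Fitting a Gaussian to that copula gives a closed-form MI estimate,

    MI(X, Y) = 1/2 * log2( |S_X| |S_Y| / |S_XY| )   [bits],

which is a lower bound on the true MI (the Gaussian is the maximum-entropy
distribution for a given covariance). Because the transform is rank-based,
the estimate is exactly invariant under strictly monotone per-dimension
transformations of the inputs.

All entropies and MI values are in bits (log base 2).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtri, psi

__all__ = [
    "MultivariateSample",
    "GaussianCopulaSample",
    "EntropyValue",
    "MIValue",
    "copula_transform",
    "gaussian_entropy",
    "gaussian_mi",
    "gcmi",
    "rescale_mi",
]

_LOG2E = np.log2(np.e)

# Relative eigenvalue floor below which a covariance gets one shot of jitter.
_JITTER_REL = 1e-10


def _as_2d(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[np.newaxis, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a dimensions x observations matrix, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class MultivariateSample:
    """A k-dimensional sample: rows are dimensions, columns are observations.

    Parameters
    ----------
    values : ndarray, shape (k, n)
        Real-valued data, no missing values, n >= 2.
    labels : tuple of str, optional
        Per-dimension identifiers used in error messages.
    """

    values: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = _as_2d(self.values)
        object.__setattr__(self, "values", arr)
        if arr.shape[1] < 2:
            raise ValueError(f"need at least 2 observations, got n={arr.shape[1]}")
        if not np.isfinite(arr).all():
            raise ValueError("sample contains NaN or infinite values")
        if self.labels is not None and len(self.labels) != arr.shape[0]:
            raise ValueError("labels length does not match number of dimensions")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def dimension_name(self, i: int) -> str:
        return self.labels[i] if self.labels is not None else f"dim {i}"


@dataclass(frozen=True)
class GaussianCopulaSample:
    """Rank-Gaussianized version of a :class:`MultivariateSample`.

    Each row is marginally standard normal by construction: sorted, it equals
    the fixed quantile grid ndtri(rank / (n + 1)). ``source_hash`` links the
    transform back to the raw sample it came from.
    """

    values: np.ndarray
    source_hash: str = ""

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EntropyValue:
    """Differential entropy in bits, with the estimator that produced it."""

    value: float
    estimator_tag: str = "closed_form_gaussian"
    dims: int = 1


@dataclass(frozen=True)
class MIValue:
    """Mutual information in bits between a k_X- and a k_Y-dimensional block."""

    value: float
    estimator_tag: str = "closed_form_gaussian"
    dims: tuple[int, int] = (1, 1)

    def __float__(self) -> float:
        return float(self.value)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def copula_transform(
    sample: MultivariateSample | np.ndarray, tie_rule: str = "average"
) -> GaussianCopulaSample:
    """Map each dimension to a standard-normal marginal via its empirical CDF.

    Every row is independently ranked, ranks are scaled to rank/(n+1) (so no
    quantile is pushed to +-infinity), and the standard-normal quantile
    function is applied. The output depends on the input only through the
    per-dimension ranks, hence is invariant under strictly increasing
    per-dimension transforms.

    Parameters
    ----------
    sample : MultivariateSample or ndarray (k, n)
    tie_rule : {"average", "ordinal"}
        How tied values are ranked. ``average`` gives tied entries equal
        output; ``ordinal`` breaks ties by position.
    """
    if not isinstance(sample, MultivariateSample):
        sample = MultivariateSample(sample)
    if sample.n < 3:
        raise ValueError(f"copula transform needs n >= 3 observations, got n={sample.n}")
    if tie_rule not in ("average", "ordinal"):
        raise ValueError(f"tie_rule must be 'average' or 'ordinal', got {tie_rule!r}")

    x = sample.values
    n = sample.n
    spans = x.max(axis=1) - x.min(axis=1)
    if np.any(spans == 0.0):
        i = int(np.argmax(spans == 0.0))
        raise ValueError(
            f"dimension {sample.dimension_name(i)!r} is constant; "
            "its empirical CDF is degenerate"
        )
    ranks = stats.rankdata(x, method=tie_rule, axis=1)
    out = ndtri(ranks / (n + 1.0))
    return GaussianCopulaSample(values=out, source_hash=_hash_array(x))


def _checked_covariance(cov: np.ndarray, what: str = "covariance") -> tuple[np.ndarray, float]:
    """Validate symmetry/PD-ness; apply one shot of diagonal jitter if needed.

    Returns the (possibly jittered) matrix and its log2-determinant.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"{what} must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError(f"{what} is not symmetric")
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    tr = float(np.trace(cov))
    if eigmin < _JITTER_REL * tr:
        cov = cov + _JITTER_REL * tr * np.eye(cov.shape[0])
        eigmin = float(np.linalg.eigvalsh(cov)[0])
        if eigmin <= 0:
            raise np.linalg.LinAlgError(
                f"{what} is not positive definite even after jitter; "
                f"smallest eigenvalue {eigmin:.3e}"
            )
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError(f"{what} has non-positive determinant")
    return cov, logdet * _LOG2E


def gaussian_entropy(cov: np.ndarray) -> EntropyValue:
    """Closed-form differential entropy of a multivariate normal, in bits.

    H = 1/2 * log2( (2 pi e)^k * |cov| ).
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    _, logdet2 = _checked_covariance(cov)
    k = cov.shape[0]
    value = 0.5 * (k * np.log2(2.0 * np.pi * np.e) + logdet2)
    return EntropyValue(value=float(value), estimator_tag="closed_form_gaussian", dims=k)


def gaussian_mi(cov_x: np.ndarray, cov_y: np.ndarray, cov_joint: np.ndarray) -> MIValue:
    """MI in bits between two jointly Gaussian blocks from their covariances.

    MI = 1/2 * log2( |S_X| |S_Y| / |S_XY| ). The joint covariance must carry
    ``cov_x`` and ``cov_y`` as its diagonal blocks; this is checked, and the
    result agrees with H(X) + H(Y) - H(X, Y) to machine precision.
    """
    cov_x = np.atleast_2d(np.asarray(cov_x, dtype=float))
    cov_y = np.atleast_2d(np.asarray(cov_y, dtype=float))
    cov_joint = np.atleast_2d(np.asarray(cov_joint, dtype=float))
    kx, ky = cov_x.shape[0], cov_y.shape[0]
    if cov_joint.shape != (kx + ky, kx + ky):
        raise ValueError(
            f"joint covariance must be {(kx + ky, kx + ky)}, got {cov_joint.shape}"
        )
    if not (
        np.allclose(cov_joint[:kx, :kx], cov_x, atol=1e-8)
        and np.allclose(cov_joint[kx:, kx:], cov_y, atol=1e-8)
    ):
        raise ValueError("diagonal blocks of the joint covariance do not match cov_x/cov_y")
    _, ld_x = _checked_covariance(cov_x, "cov_x")
    _, ld_y = _checked_covariance(cov_y, "cov_y")
    _, ld_xy = _checked_covariance(cov_joint, "cov_joint")
    value = 0.5 * (ld_x + ld_y - ld_xy)
    return MIValue(value=float(value), estimator_tag="closed_form_gaussian", dims=(kx, ky))


def _mvn_entropy_bias_bits(n: int, k: int) -> float:
    """Finite-sample bias of the log-determinant Gaussian entropy, in bits.

    The sample covariance determinant is biased; the expectation of
    log |C_hat| exceeds log |C| by sum_i psi((n-i)/2) + k*log(2/(n-1)) in
    nats (Wishart moments), giving the standard digamma-style correction.
    """
    i = np.arange(1, k + 1)
    nats = float(np.sum(psi((n - i) / 2.0))) + k * np.log(2.0 / (n - 1.0))
    return 0.5 * nats * _LOG2E


def gcmi(
    x: MultivariateSample | np.ndarray,
    y: MultivariateSample | np.ndarray,
    bias_correction: bool = False,
    tie_rule: str = "average",
) -> MIValue:
    """Gaussian-copula MI estimate between two aligned multivariate samples.

    Both samples are copula-transformed dimension-wise, the joint covariance
    of the transformed data is estimated with 1/(n-1) normalisation, and the
    closed-form Gaussian MI of the two blocks is returned. Negative raw
    estimates (possible from sampling noise) are clipped to zero with a
    warning.

    Parameters
    ----------
    x, y : MultivariateSample or ndarray (k, n)
        Aligned observations; must share n, and k_X + k_Y < n.
    bias_correction : bool
        Apply the digamma finite-sample correction to each log-determinant
        entropy. Off by default so the estimate matches the closed form
        literally.
    """
    if not isinstance(x, MultivariateSample):
        x = MultivariateSample(x)
    if not isinstance(y, MultivariateSample):
        y = MultivariateSample(y)
    if x.n != y.n:
        raise ValueError(f"samples must share observations: n_x={x.n}, n_y={y.n}")
    n, kx, ky = x.n, x.k, y.k
    if kx + ky >= n:
        raise ValueError(
            f"need k_X + k_Y < n for a full-rank copula covariance; "
            f"got k_X + k_Y = {kx + ky} >= n = {n}"
        )

    zx = copula_transform(x, tie_rule=tie_rule).values
    zy = copula_transform(y, tie_rule=tie_rule).values
    z = np.vstack([zx, zy])
    cov = np.cov(z)  # 1/(n-1) normalisation
    cov = np.atleast_2d(cov)

    mi = gaussian_mi(cov[:kx, :kx], cov[kx:, kx:], cov).value
    if bias_correction:
        # MI = H(X) + H(Y) - H(X,Y); the additive entropy biases partially cancel.
        mi -= (
            _mvn_entropy_bias_bits(n, kx)
            + _mvn_entropy_bias_bits(n, ky)
            - _mvn_entropy_bias_bits(n, kx + ky)
        )
    if mi < 0.0:
        if mi < -1e-6:
            warnings.warn(
                f"negative raw MI estimate ({mi:.3e} bits) clipped to 0", stacklevel=2
            )
        mi = 0.0
    return MIValue(value=float(mi), estimator_tag="gaussian_copula", dims=(kx, ky))


def rescale_mi(mi: MIValue | float) -> float:
    """Map an MI value in bits onto a correlation-scale magnitude in [0, 1).

    Inverts the univariate Gaussian relation MI = -1/2*log2(1 - r^2), i.e.
    returns sqrt(1 - 2^(-2*MI)): strictly increasing, 0 -> 0, infinity -> 1.
    For univariate Gaussian data the result recovers |r| exactly.
    """
    value = float(mi)
    if value < 0:
        raise ValueError(f"MI must be nonnegative, got {value}")
    return float(np.sqrt(1.0 - 2.0 ** (-2.0 * value)))
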