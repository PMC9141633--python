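"""Copula transform, closed-form Gaussian entropy/MI, and the GCMI estimator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from copulafc import (
    MultivariateSample,
    copula_transform,
    gaussian_entropy,
    gaussian_mi,
    gcmi,
    rescale_mi,
)

H1 = 0.5 * np.log2(2 * np.pi * np.e)  # univariate unit-variance entropy, bits


class TestCopulaTransform:
    def test_three_point_row_hits_normal_quantiles(self):
        out = copula_transform(np.array([[10.0, 20.0, 30.0]]))
        expected = ndtri([0.25, 0.5, 0.75])
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)
        assert abs(out.values[0][1]) < 1e-12

    def test_invariant_under_monotone_map(self, rng):
        x = rng.normal(size=(3, 50))
        a = copula_transform(x).values
        b = copula_transform(np.exp(x)).values
        np.testing.assert_array_equal(a, b)

    def test_ties_get_equal_values_under_average_rule(self):
        out = copula_transform(np.array([[1.0, 2.0, 2.0, 5.0]]), tie_rule="average")
        assert out.values[0, 1] == out.values[0, 2]
        ordinal = copula_transform(np.array([[1.0, 2.0, 2.0, 5.0]]), tie_rule="ordinal")
        assert ordinal.values[0, 1] != ordinal.values[0, 2]

    def test_rows_are_marginally_standard_normal(self, rng):
        out = copula_transform(rng.normal(size=(4, 500))).values
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=0.05)
        # every row, sorted, is the same fixed quantile grid
        ref = np.sort(out[0])
        for row in out[1:]:
            np.testing.assert_allclose(np.sort(row), ref, atol=1e-12)

    def test_constant_row_names_dimension(self):
        data = np.vstack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="flat"):
            copula_transform(MultivariateSample(data, labels=("ok", "flat")))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN|missing|finite"):
            MultivariateSample(np.array([[1.0, np.nan, 3.0]]))


class TestClosedForms:
    def test_univariate_unit_variance_entropy(self):
        assert gaussian_entropy([[1.0]]).value == pytest.approx(2.0471, abs=1e-4)

    def test_independent_bivariate_entropy_is_additive(self):
        assert gaussian_entropy(np.eye(2)).value == pytest.approx(2 * H1, abs=1e-12)

    def test_variance_four_adds_one_bit(self):
        assert gaussian_entropy([[4.0]]).value == pytest.approx(H1 + 1.0, abs=1e-12)

    def test_non_pd_reports_smallest_eigenvalue(self):
        with pytest.raises(np.linalg.LinAlgError, match="eigenvalue"):
            gaussian_entropy([[1.0, 2.0], [2.0, 1.0]])

    @pytest.mark.parametrize("r", [0.0, 0.2, 0.5, 0.8])
    def test_univariate_mi_matches_correlation_form(self, r):
        joint = np.array([[1.0, r], [r, 1.0]])
        expected = -0.5 * np.log2(1 - r**2)
        assert gaussian_mi([[1.0]], [[1.0]], joint).value == pytest.approx(expected, abs=1e-12)

    def test_mi_is_even_in_correlation(self):
        plus = gaussian_mi([[1.0]], [[1.0]], [[1.0, 0.5], [0.5, 1.0]]).value
        minus = gaussian_mi([[1.0]], [[1.0]], [[1.0, -0.5], [-0.5, 1.0]]).value
        assert plus == pytest.approx(minus, abs=1e-14)

    def test_entropy_decomposition_identity(self, rng):
        """MI from the determinant ratio equals H(X)+H(Y)-H(X,Y)."""
        for _ in range(25):
            kx, ky = rng.integers(1, 4, size=2)
            a = rng.normal(size=(kx + ky, kx + ky + 2))
            joint = a @ a.T + 0.1 * np.eye(kx + ky)
            cx, cy = joint[:kx, :kx], joint[kx:, kx:]
            via_det = gaussian_mi(cx, cy, joint).value
            via_h = (
                gaussian_entropy(cx).value
                + gaussian_entropy(cy).value
                - gaussian_entropy(joint).value
            )
            assert via_det == pytest.approx(via_h, abs=1e-10)

    def test_block_mismatch_rejected(self):
        joint = np.array([[2.0, 0.1], [0.1, 1.0]])
        with pytest.raises(ValueError, match="block"):
            gaussian_mi([[1.0]], [[1.0]], joint)


class TestGCMI:
    def test_recovers_mi_of_bivariate_gaussian(self, gaussian_pair):
        x, y = gaussian_pair
        expected = -0.5 * np.log2(1 - 0.25)
        assert gcmi(x, y).value == pytest.approx(expected, abs=0.05)

    def test_rank_invariance_is_exact(self, gaussian_pair):
        x, y = gaussian_pair
        assert gcmi(np.exp(x), y).value == gcmi(x, y).value
        assert gcmi(x, y**3).value == gcmi(x, y).value

    def test_independent_shuffle_near_zero(self, rng):
        x = rng.normal(size=(1, 3000))
        y = rng.permutation(x[0])[np.newaxis, :]
        assert gcmi(x, y).value < 0.005

    def test_nonnegative_by_construction(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            assert gcmi(r.normal(size=(1, 50)), r.normal(size=(1, 50))).value >= 0.0

    def test_mismatched_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n_x=50"):
            gcmi(rng.normal(size=(1, 50)), rng.normal(size=(1, 60)))

    def test_too_many_dimensions_rejected(self, rng):
        with pytest.raises(ValueError, match="full-rank"):
            gcmi(rng.normal(size=(5, 8)), rng.normal(size=(5, 8)))

    def test_bias_correction_shrinks_small_sample_estimate(self, rng):
        """On independent data the raw estimator is biased up; the digamma
        correction removes most of that bias."""
        raw, corrected = [], []
        for seed in range(40):
            r = np.random.default_rng(seed)
            x, y = r.normal(size=(1, 60)), r.normal(size=(1, 60))
            raw.append(gcmi(x, y).value)
            corrected.append(gcmi(x, y, bias_correction=True).value)
        assert np.mean(corrected) < np.mean(raw)

    def test_lower_bound_versus_knn_oracle_on_heavy_tails(self, rng):
        """On t-copula data with heavy tails the Gaussian-copula estimate
        should not exceed an independent KNN MI estimate beyond its spread."""
        from sklearn.feature_selection import mutual_info_regression

        df, r, n = 3, 0.6, 2000
        cov = np.array([[1.0, r], [r, 1.0]])
        gaps = []
        for seed in range(5):
            rr = np.random.default_rng(seed)
            z = rr.multivariate_normal([0, 0], cov, size=n)
            chi = rr.chisquare(df, size=n) / df
            t = z / np.sqrt(chi)[:, np.newaxis]  # bivariate t: tail-dependent
            gc = gcmi(t[:, :1].T, t[:, 1:].T).value
            knn = mutual_info_regression(
                t[:, :1], t[:, 1], n_neighbors=5, random_state=seed
            )[0] / np.log(2)
            gaps.append(gc - knn)
        assert np.mean(gaps) < 0.05


class TestRescale:
    def test_zero_maps_to_zero(self):
        assert rescale_mi(0.0) == 0.0

    def test_inverts_half_correlation(self):
        assert rescale_mi(-0.5 * np.log2(1 - 0.25)) == pytest.approx(0.5, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rescale_mi(-0.1)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(0.0, 8.0, allow_nan=False),
        st.floats(1e-3, 5.0, allow_nan=False),
    )
    def test_strictly_increasing_and_bounded(self, mi, delta):
        # domain limited to where float64 can still resolve 1 - 2^(-2*mi)
        lo, hi = rescale_mi(mi), rescale_mi(mi + delta)
        assert 0.0 <= lo < 1.0 and 0.0 <= hi < 1.0
        assert hi > lo
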