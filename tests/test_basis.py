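"""Spline, Fourier and cross-basis construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlnmkit.basis import (
    CrossBasisSpec,
    RankError,
    SpecError,
    SplineSpec,
    build_cross_basis,
    fourier_basis,
    natural_cubic_basis,
)
from conftest import brute_force_cross_basis, truncated_power_natural_basis


def _span_distance(A, B):
    """Max residual of projecting each matrix onto the other's column span."""
    def resid(M, target):
        coef, *_ = np.linalg.lstsq(M, target, rcond=None)
        return np.abs(M @ coef - target).max()
    one = np.ones((A.shape[0], 1))
    return max(resid(np.hstack([one, A]), B), resid(np.hstack([one, B]), A))


class TestNaturalCubicBasis:
    def test_df1_is_linear(self):
        x = np.linspace(2.0, 9.0, 40)
        B = natural_cubic_basis(x, SplineSpec(df=1))
        assert B.shape == (40, 1)
        # single column is an affine function of x
        design = np.column_stack([np.ones(40), x])
        coef, *_ = np.linalg.lstsq(design, B[:, 0], rcond=None)
        assert np.abs(design @ coef - B[:, 0]).max() < 1e-10

    def test_constant_input_raises(self):
        with pytest.raises(RankError):
            natural_cubic_basis(np.full(20, 3.0), SplineSpec(df=2))

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(RankError):
            natural_cubic_basis(np.array([0.0, 1.0, 0.0, 1.0]),
                                SplineSpec(df=4))

    def test_invalid_df_raises(self):
        with pytest.raises(SpecError):
            SplineSpec(df=0)

    def test_linear_functions_in_span(self):
        # natural splines are linear beyond the boundary, so y = x must be
        # reproduced exactly by least squares on basis + intercept
        x = np.arange(11.0)
        B = natural_cubic_basis(x, SplineSpec(df=3))
        design = np.column_stack([np.ones(11), B])
        coef, *_ = np.linalg.lstsq(design, x, rcond=None)
        assert np.abs(design @ coef - x).max() < 1e-9

    @pytest.mark.parametrize("df", [2, 3, 4, 5])
    def test_span_matches_truncated_power_oracle(self, df, rng):
        x = rng.uniform(0.0, 50.0, 120)
        lo, hi = x.min(), x.max()
        spec = SplineSpec(df=df)
        B = natural_cubic_basis(x, spec)
        assert B.shape == (120, df)
        oracle = truncated_power_natural_basis(
            x, spec.interior_knots(lo, hi), lo, hi
        )
        assert _span_distance(B, oracle) < 1e-7

    def test_natural_tails_are_linear(self):
        # second differences vanish outside the boundary knots
        x = np.linspace(10.0, 20.0, 30)
        spec = SplineSpec(df=4, boundary=(10.0, 20.0))
        outside = np.linspace(21.0, 30.0, 50)
        B = natural_cubic_basis(outside, spec)
        second_diff = np.diff(B, n=2, axis=0)
        assert np.abs(second_diff).max() < 1e-9

    def test_interior_knot_count(self):
        spec = SplineSpec(df=5)
        assert len(spec.interior_knots(0.0, 1.0)) == 4
        assert len(SplineSpec(df=1).interior_knots(0.0, 1.0)) == 0


class TestFourierBasis:
    def test_six_harmonics_give_twelve_columns(self):
        sb = fourier_basis(np.arange(400), m=365, K=6)
        assert sb.matrix.shape == (400, 12)
        assert np.abs(sb.matrix).max() <= 1.0 + 1e-12

    def test_phase_zero_row(self):
        sb = fourier_basis([0], m=365, K=6)
        expected = np.tile([0.0, 1.0], 6)
        np.testing.assert_allclose(sb.matrix[0], expected, atol=1e-12)

    def test_annual_periodicity(self):
        sb = fourier_basis([3, 3 + 365], m=365, K=4)
        np.testing.assert_allclose(sb.matrix[0], sb.matrix[1], atol=1e-12)

    @pytest.mark.parametrize("m,K", [(0, 3), (365, 0), (-1, 2)])
    def test_invalid_spec(self, m, K):
        with pytest.raises(SpecError):
            fourier_basis(np.arange(10), m=m, K=K)


class TestCrossBasis:
    def test_matches_brute_force(self, rng):
        x = rng.uniform(5.0, 80.0, 50)
        spec = CrossBasisSpec(max_lag=5, df_p=3, df_l=3)
        cb = build_cross_basis(x, spec)
        R = cb.predictor_basis(x)
        C = cb.lag_basis()
        oracle = brute_force_cross_basis(x, R, C, 5)
        np.testing.assert_allclose(cb.matrix, oracle, atol=1e-10)

    def test_no_lag_collapse(self, rng):
        x = rng.uniform(0.0, 10.0, 30)
        spec = CrossBasisSpec(max_lag=0, df_p=3, df_l=1)
        cb = build_cross_basis(x, spec)
        np.testing.assert_allclose(cb.matrix, cb.predictor_basis(x),
                                   atol=1e-12)

    def test_constant_exposure_rows_identical(self):
        # constant series: every usable row equals R(c)_j * sum_l C(l)_k
        x = np.full(40, 25.0)
        spec = CrossBasisSpec(max_lag=4, df_p=2, df_l=2)
        cb = build_cross_basis(x, spec)
        assert np.abs(cb.matrix - cb.matrix[0]).max() < 1e-12

    def test_dimension_bookkeeping(self, rng):
        x = rng.uniform(0.0, 60.0, 80)
        spec = CrossBasisSpec(max_lag=7, df_p=4, df_l=2)
        cb = build_cross_basis(x, spec)
        assert cb.matrix.shape == (80 - 7, 4 * 2)
        assert list(cb.usable_index) == list(range(7, 80))

    def test_series_shorter_than_window_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            build_cross_basis(np.arange(5.0), CrossBasisSpec(7, 2, 2))

    def test_linearity_in_predictor_basis(self, rng):
        # doubling the exposure basis contribution doubles the cross-basis:
        # realized through beta-space equivalence of scaled coefficients
        x = rng.uniform(10.0, 70.0, 60)
        spec = CrossBasisSpec(max_lag=3, df_p=3, df_l=2)
        cb = build_cross_basis(x, spec)
        beta = rng.normal(size=spec.n_columns)
        np.testing.assert_allclose(cb.matrix @ (2 * beta),
                                   2 * (cb.matrix @ beta), atol=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        L=st.integers(1, 10),
        df_p=st.integers(2, 5),
        df_l=st.integers(2, 5),
        seed=st.integers(0, 2**16),
    )
    def test_brute_force_property(self, L, df_p, df_l, seed):
        g = np.random.default_rng(seed)
        x = g.uniform(0.0, 100.0, 40 + L)
        spec = CrossBasisSpec(max_lag=L, df_p=df_p, df_l=df_l)
        cb = build_cross_basis(x, spec)
        assert cb.matrix.shape == (40, df_p * df_l)
        oracle = brute_force_cross_basis(x, cb.predictor_basis(x),
                                         cb.lag_basis(), L)
        np.testing.assert_allclose(cb.matrix, oracle, atol=1e-10)
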