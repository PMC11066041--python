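"""Reduction of fitted cross-basis blocks to relative-risk summaries."""

import numpy as np
import pytest

from dlnmkit.association import (
    ShapeError,
    default_grid,
    exposure_lag_surface,
    extreme_effects,
    overall_cumulative,
)
from dlnmkit.basis import CrossBasis, CrossBasisSpec, build_cross_basis
from dlnmkit.meta_pool import PooledEstimate


def _pooled(beta, vcov):
    return PooledEstimate(beta_pooled=np.asarray(beta, dtype=float),
                          vcov_pooled=np.asarray(vcov, dtype=float))


@pytest.fixture(scope="module")
def cb():
    rng = np.random.default_rng(5)
    x = rng.uniform(10.0, 80.0, 200)
    return build_cross_basis(x, CrossBasisSpec(max_lag=3, df_p=2, df_l=2))


class TestOverallCumulative:
    def test_reference_identity_is_exact(self, small_fit):
        fit, cb, panel, _ = small_fit
        x_ref = float(np.median(panel["x"]))
        a = overall_cumulative(fit, cb, [x_ref], x_ref)
        assert a.table["log_rr"].iloc[0] == 0.0
        assert a.table["se"].iloc[0] == 0.0
        assert a.table["rr"].iloc[0] == 1.0

    def test_null_coefficients_give_flat_curve(self, cb):
        d = cb.spec.n_columns
        est = _pooled(np.zeros(d), 0.01 * np.eye(d))
        a = overall_cumulative(est, cb, np.linspace(15, 75, 9), 40.0)
        np.testing.assert_allclose(a.table["rr"], 1.0, atol=1e-12)

    def test_ci_ordering_and_nonnegative_se(self, small_fit):
        fit, cb, panel, _ = small_fit
        grid = default_grid(panel["x"], 30)
        a = overall_cumulative(fit, cb, grid, float(np.median(panel["x"])))
        assert (a.table["se"] >= 0).all()
        assert (a.table["rr_low"] <= a.table["rr"]).all()
        assert (a.table["rr"] <= a.table["rr_high"]).all()

    def test_matches_lag_sum_of_surface(self, small_fit):
        # definitional consistency: summing surface log-RR over integer
        # lags reproduces the overall cumulative curve
        fit, cb, panel, _ = small_fit
        x_ref = float(np.median(panel["x"]))
        grid = np.linspace(panel["x"].min(), panel["x"].max(), 7)
        overall = overall_cumulative(fit, cb, grid, x_ref)
        surf = exposure_lag_surface(fit, cb, grid, x_ref=x_ref)
        summed = surf.table.groupby("x", sort=True)["log_rr"].sum()
        np.testing.assert_allclose(
            overall.table.sort_values("x")["log_rr"].to_numpy(),
            summed.to_numpy(), atol=1e-10,
        )

    def test_dimension_mismatch_raises(self, cb):
        bad = _pooled(np.zeros(3), np.eye(3))
        with pytest.raises(ShapeError):
            overall_cumulative(bad, cb, [20.0], 40.0)


class TestSurface:
    def test_reference_row_is_unity_across_lags(self, small_fit):
        fit, cb, panel, _ = small_fit
        x_ref = float(np.median(panel["x"]))
        surf = exposure_lag_surface(fit, cb, [x_ref], x_ref=x_ref)
        np.testing.assert_allclose(surf.table["rr"], 1.0, atol=1e-12)
        assert len(surf.table) == cb.spec.max_lag + 1

    def test_long_format_columns(self, small_fit):
        fit, cb, panel, _ = small_fit
        surf = exposure_lag_surface(fit, cb, [20.0, 40.0],
                                    x_ref=float(np.median(panel["x"])))
        assert {"x", "lag", "rr", "rr_low", "rr_high"} <= set(
            surf.table.columns)
        assert sorted(surf.table["lag"].unique()) == list(
            range(cb.spec.max_lag + 1))

    def test_estimation_error_shrinks_with_more_data(self):
        # consistency: mean absolute log-RR error against the known truth
        # decreases from a 2-year to an 8-year panel (fixed seeds)
        from dlnmkit import CandidateModel, SimConfig, fit_frozen, simulate_panel

        errors = {"short": [], "long": []}
        for seed in range(6):
            for years, end in (("short", "2017-12-31"),
                               ("long", "2023-12-31")):
                cfg = SimConfig(n_cities=1, end_date=end, seed=seed)
                panel, surf_true = simulate_panel(cfg)
                cand = CandidateModel(covariate_mask=("tavg",),
                                      max_lag=surf_true.max_lag, df_p=4,
                                      df_l=4)
                fit, cb = fit_frozen(panel, cand)
                x = panel["x"].to_numpy()
                grid = np.linspace(np.quantile(x, 0.05),
                                   np.quantile(x, 0.95), 15)
                a = overall_cumulative(fit, cb, grid, surf_true.x_ref)
                errors[years].append(np.abs(
                    a.table["log_rr"].to_numpy()
                    - surf_true.cumulative(grid)
                ).mean())
        assert np.mean(errors["long"]) < np.mean(errors["short"])


class TestExtremeEffects:
    def test_self_contrast_is_unity(self, small_fit):
        fit, cb, panel, _ = small_fit
        ec = extreme_effects(fit, cb, panel["x"], levels=(0.5, 0.5, 0.5))
        np.testing.assert_allclose(ec.table["rr"], 1.0, atol=1e-12)

    def test_null_block_gives_unity_with_symmetric_ci(self, cb):
        d = cb.spec.n_columns
        est = _pooled(np.zeros(d), 0.02 * np.eye(d))
        rng = np.random.default_rng(0)
        ec = extreme_effects(est, cb, rng.uniform(10, 80, 500))
        np.testing.assert_allclose(ec.table["rr"], 1.0, atol=1e-12)
        np.testing.assert_allclose(
            ec.table["rr"] / ec.table["rr_low"],
            ec.table["rr_high"] / ec.table["rr"], rtol=1e-10,
        )

    def test_lag_axis_covers_window(self, small_fit):
        fit, cb, panel, _ = small_fit
        ec = extreme_effects(fit, cb, panel["x"])
        for _, g in ec.table.groupby("contrast"):
            assert list(g["lag"]) == list(range(cb.spec.max_lag + 1))

    def test_degenerate_series_raises(self, small_fit):
        fit, cb, _, _ = small_fit
        with pytest.raises(ValueError, match="degenerate|empty"):
            extreme_effects(fit, cb, np.full(100, 30.0))

    def test_decaying_lag_weights_show_in_contrast(self, small_fit):
        # truth lag weight decays geometrically, so the magnitude of the
        # high-vs-median contrast should fade across lags: compare the
        # first to the last third of the lag axis with CI slack
        fit, cb, panel, _ = small_fit
        ec = extreme_effects(fit, cb, panel["x"])
        hi = ec.table[ec.table["contrast"] == "high_vs_median"]
        mag = np.abs(hi["log_rr"].to_numpy())
        half = np.abs(np.log(hi["rr_high"].to_numpy())
                      - hi["log_rr"].to_numpy())
        early = mag[:3].mean()
        late = mag[-3:].mean()
        assert late <= early + half.mean()
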