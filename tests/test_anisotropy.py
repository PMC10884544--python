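"""sin^4(theta) representation, AIC selection, binning, smoothing spline,
variance contribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from b0dti import (
    RelaxationModel,
    Sin4AnisotropyModel,
    bin_average,
    fit_sin4,
    relaxation_rate,
    spline_anisotropy,
    variance_contribution,
)
from b0dti.anisotropy import aic_least_squares, delta_aic_support

THETA_GRID = np.arange(91.0)
SIN4 = np.sin(np.radians(THETA_GRID)) ** 4


class TestSin4Fit:
    def test_constant_data_is_isotropic(self):
        res = fit_sin4(THETA_GRID, np.full(91, 3.2))
        assert res.a_hat == pytest.approx(3.2)
        assert res.b_hat == pytest.approx(0.0, abs=1e-12)
        assert res.selected == "isotropic"

    def test_recovers_extra_axonal_relaxation_parameters(self):
        """R2(theta) = 17.4 + 2.4 sin^4(theta) must be recovered exactly."""
        rates = relaxation_rate(RelaxationModel("sin4", 17.4, 2.4), THETA_GRID)
        res = fit_sin4(THETA_GRID, rates)
        assert res.a_hat == pytest.approx(17.4, abs=1e-12)
        assert res.b_hat == pytest.approx(2.4, abs=1e-12)
        assert res.selected == "anisotropic"

    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    @settings(max_examples=40, derandomize=True)
    def test_noiseless_recovery_any_coefficients(self, a, b):
        res = fit_sin4(THETA_GRID, a + b * SIN4)
        assert res.a_hat == pytest.approx(a, abs=1e-9)
        assert res.b_hat == pytest.approx(b, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        """Noisy fit must agree with brute-force SSE minimisation over (A, B)."""
        rng = np.random.default_rng(99)
        theta = rng.uniform(0, 90, 500)
        y = 1.0 + 0.5 * np.sin(np.radians(theta)) ** 4 + rng.normal(0, 0.1, 500)
        res = fit_sin4(theta, y)
        s4 = np.sin(np.radians(theta)) ** 4
        a_grid = np.arange(res.a_hat - 0.05, res.a_hat + 0.05, 1e-3)
        b_grid = np.arange(res.b_hat - 0.05, res.b_hat + 0.05, 1e-3)
        sse = (
            (y[None, None, :] - a_grid[:, None, None] - b_grid[None, :, None] * s4) ** 2
        ).sum(axis=-1)
        ia, ib = np.unravel_index(np.argmin(sse), sse.shape)
        assert res.a_hat == pytest.approx(a_grid[ia], abs=1e-3)
        assert res.b_hat == pytest.approx(b_grid[ib], abs=1e-3)

    def test_weighted_fit_matches_replication(self, rng):
        theta = np.array([0.0, 20.0, 45.0, 70.0, 90.0])
        y = rng.normal(1.0, 0.2, 5)
        w = np.array([1, 3, 2, 1, 5])
        res_w = Sin4AnisotropyModel(theta, y, weights=w).fit()
        rep_theta = np.repeat(theta, w)
        rep_y = np.repeat(y, w)
        res_rep = fit_sin4(rep_theta, rep_y)
        assert res_w.a_hat == pytest.approx(res_rep.a_hat, abs=1e-10)
        assert res_w.b_hat == pytest.approx(res_rep.b_hat, abs=1e-10)

    def test_identical_theta_rejected(self):
        with pytest.raises(ValueError):
            fit_sin4(np.full(10, 45.0), np.arange(10.0))


class TestAicSelection:
    def test_penalty_arithmetic(self):
        # equal residual sums, one extra parameter -> dAIC = 2, isotropic kept
        assert aic_least_squares(1.0, 50, 2) - aic_least_squares(1.0, 50, 1) == pytest.approx(2.0)

    def test_ci_containing_zero_forces_isotropic(self, rng):
        # strong-looking trend but tiny n so the 85% CI straddles zero
        theta = np.array([0.0, 30.0, 60.0, 90.0])
        y = np.array([0.0, 0.05, -0.05, 0.1])
        res = fit_sin4(theta, y)
        lo, hi = res.b_ci85
        if lo <= 0 <= hi:
            assert res.selected == "isotropic"

    def test_strong_anisotropy_selected_with_no_support_for_iso(self):
        rng = np.random.default_rng(3)
        y = 1.0 + 2.0 * SIN4 + rng.normal(0, 0.05, 91)
        res = fit_sin4(THETA_GRID, y)
        assert res.selected == "anisotropic"
        assert res.delta_aic >= 10
        assert res.support_label == "none"

    def test_selection_never_anisotropic_with_zero_in_ci(self, rng):
        for seed in range(200):
            r = np.random.default_rng(seed)
            y = r.normal(0, 1, 30)
            theta = r.uniform(0, 90, 30)
            res = fit_sin4(theta, y)
            lo, hi = res.b_ci85
            if lo <= 0 <= hi:
                assert res.selected == "isotropic"

    def test_type_one_error_rate_below_15_percent(self):
        """Joint dAIC + CI rule on theta-independent Gaussian data."""
        hits = 0
        n_rep = 1000
        for seed in range(n_rep):
            r = np.random.default_rng(10_000 + seed)
            theta = r.uniform(0, 90, 91)
            y = r.normal(0.0, 1.0, 91)
            if fit_sin4(theta, y).selected == "anisotropic":
                hits += 1
        assert hits / n_rep < 0.15

    def test_support_bands(self):
        assert delta_aic_support(1.0) == "substantial"
        assert delta_aic_support(5.0) == "considerably_less"
        assert delta_aic_support(12.0) == "none"


class TestBinAverage:
    def test_single_bin_collapse(self):
        t = np.array([10.2, 10.5, 10.9])
        v = np.array([1.0, 2.0, 3.0])
        out = bin_average(t, v)
        assert len(out) == 1
        assert out["theta_mean"].iloc[0] == pytest.approx(t.mean())
        assert out["value_mean"].iloc[0] == pytest.approx(2.0)
        assert out["count"].iloc[0] == 3

    def test_half_open_edge_convention(self):
        out = bin_average(np.array([1.0, 0.999]), np.array([5.0, 7.0]))
        assert set(out["bin"]) == {0, 1}  # point at 1.0 goes to bin [1, 2)

    def test_top_edge_folds_into_last_bin(self):
        out = bin_average(np.array([90.0]), np.array([1.0]))
        assert out["bin"].iloc[0] == 89

    def test_matches_groupby_oracle(self, rng):
        theta = rng.uniform(0, 90, 2000)
        vals = rng.normal(size=2000)
        out = bin_average(theta, vals)
        oracle = (
            pd.DataFrame({"k": np.floor(theta).astype(int), "t": theta, "v": vals})
            .groupby("k")
            .agg(t=("t", "mean"), v=("v", "mean"), n=("v", "size"))
        )
        assert np.array_equal(out["bin"].to_numpy(), oracle.index.to_numpy())
        assert np.allclose(out["theta_mean"], oracle["t"])
        assert np.allclose(out["value_mean"], oracle["v"])
        assert np.array_equal(out["count"].to_numpy(), oracle["n"].to_numpy())

    def test_rejects_bad_width(self):
        with pytest.raises(ValueError):
            bin_average(np.array([1.0, 2.0, 3.0]), np.ones(3), width=0.0)


class TestSplineAnisotropy:
    def test_recovers_positive_magnitude(self, rng):
        theta = rng.uniform(0, 90, 8000)
        vals = 1.0 + 0.5 * np.sin(np.radians(theta)) ** 4
        res = spline_anisotropy(theta, vals)
        assert res.magnitude == pytest.approx(0.5, abs=1e-3)
        assert res.variance_contribution == pytest.approx(1.0, abs=1e-3)

    def test_sign_rule_for_decreasing_curve(self, rng):
        theta = rng.uniform(0, 90, 8000)
        vals = 1.0 - 0.5 * np.sin(np.radians(theta)) ** 4
        res = spline_anisotropy(theta, vals)
        assert res.magnitude == pytest.approx(-0.5, abs=1e-3)

    @pytest.mark.parametrize("b", [0.01, 0.1, 1.0, 5.0])
    def test_magnitude_tracks_sin4_amplitude(self, b):
        theta = np.linspace(0, 90, 9001)
        res = spline_anisotropy(theta, 2.0 + b * np.sin(np.radians(theta)) ** 4)
        assert res.magnitude == pytest.approx(b, abs=1e-3)

    def test_null_data_small_magnitude(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 90, 5000)
        vals = 1.0 + rng.normal(0, 0.1, 5000)
        res = spline_anisotropy(theta, vals)
        assert abs(res.magnitude) < 0.1
        assert res.variance_contribution < 0.05

    def test_too_few_bins_raises(self):
        with pytest.raises(ValueError):
            spline_anisotropy(np.array([1.0, 2.0, 3.0] * 5), np.ones(15))


class TestVarianceContribution:
    def test_perfect_fit_gives_one(self, rng):
        v = rng.normal(size=100)
        assert variance_contribution(v, v) == pytest.approx(1.0)

    def test_constant_fit_gives_zero(self, rng):
        v = rng.normal(size=100)
        assert variance_contribution(v, np.full(100, v.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        v = rng.normal(2.0, 1.0, 500)
        fit = rng.normal(2.0, 0.5, 500)
        expected = (np.std(v) - np.std(v - fit + fit.mean())) / np.std(v)
        assert variance_contribution(v, fit) == pytest.approx(expected, abs=1e-12)

    @given(shift=st.floats(-10, 10))
    @settings(max_examples=25, derandomize=True)
    def test_invariant_to_common_shift(self, shift):
        rng = np.random.default_rng(5)
        v = rng.normal(size=200)
        fit = 0.5 * v + rng.normal(0, 0.1, 200)
        assert variance_contribution(v + shift, fit + shift) == pytest.approx(
            variance_contribution(v, fit), abs=1e-9
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_contribution(np.ones(10), np.ones(10))
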