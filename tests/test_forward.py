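"""Forward model: projections, relaxation rates, signals, analytic measures,
Watson dispersion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from b0dti import (
    MAGIC_ANGLE_DEG,
    RelaxationModel,
    TissueParams,
    adc_analytic,
    analytic_dt_measures,
    default_tissue,
    fold_angle_deg,
    kappa_to_od,
    od_to_kappa,
    project_diffusivity,
    relaxation_rate,
    signal_no_dispersion,
    signal_with_dispersion,
)
from b0dti.forward import watson_quadrature


class TestProjectDiffusivity:
    @pytest.mark.parametrize(
        "g, n, d_par, d_perp, expected",
        [
            ([1, 0, 0], [0, 0, 1], 2.0, 0.4, 0.4),  # perpendicular
            ([0, 0, 1], [0, 0, 1], 2.6, 0.0, 2.6),  # parallel
            (np.array([1, 0, 1]) / np.sqrt(2), [0, 0, 1], 2.6, 0.0, 1.3),  # 45 deg
        ],
    )
    def test_closed_form(self, g, n, d_par, d_perp, expected):
        assert project_diffusivity(g, n, d_par, d_perp) == pytest.approx(expected)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            project_diffusivity([2, 0, 0], [0, 0, 1], 2.0, 0.4)

    @given(
        ct=st.floats(-1, 1),
        d_par=st.floats(0.1, 3.0),
        d_perp=st.floats(0.0, 3.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_bounded_by_eigenvalues(self, ct, d_par, d_perp):
        g = np.array([np.sqrt(1 - ct**2), 0.0, ct])
        d = project_diffusivity(g, [0, 0, 1], d_par, d_perp)
        lo, hi = min(d_par, d_perp), max(d_par, d_perp)
        assert lo - 1e-12 <= d <= hi + 1e-12


class TestRelaxationRate:
    def test_sin4_reference_values(self):
        model = RelaxationModel("sin4", 17.4, 2.4)
        assert relaxation_rate(model, 0.0) == pytest.approx(17.4)
        assert relaxation_rate(model, 90.0) == pytest.approx(19.8)

    def test_dipolar_vanishes_at_magic_angle(self):
        model = RelaxationModel("dipolar", 0.0, 1.0)
        assert relaxation_rate(model, MAGIC_ANGLE_DEG) == pytest.approx(0.0, abs=1e-10)

    def test_magic_angle_value(self):
        assert round(MAGIC_ANGLE_DEG, 1) == 54.7

    def test_constant_is_flat(self):
        model = RelaxationModel("constant", 12.0, 0.0)
        rates = relaxation_rate(model, np.linspace(0, 90, 10))
        assert np.allclose(rates, 12.0)

    def test_rejects_unfolded_angle(self):
        with pytest.raises(ValueError):
            relaxation_rate(RelaxationModel("sin4", 17.4, 2.4), 120.0)


class TestFoldAngle:
    def test_antipodal_symmetry(self):
        assert fold_angle_deg(np.array([0.0, 0, 1]), np.array([0.0, 0, -1])) == pytest.approx(0.0)

    @given(st.floats(0, 180))
    @settings(max_examples=30, derandomize=True)
    def test_folds_into_quadrant(self, ang):
        a = np.radians(ang)
        v = np.array([np.sin(a), 0.0, np.cos(a)])
        out = fold_angle_deg(v, np.array([0.0, 0.0, 1.0]))
        assert 0.0 <= out <= 90.0
        # arccos loses ~sqrt(eps) precision near 0 and 180 degrees
        assert out == pytest.approx(min(ang, 180 - ang), abs=1e-5)


class TestSignalNoDispersion:
    def test_unity_at_origin(self, tissue):
        assert signal_no_dispersion(0.0, [0, 0, 1], 0.0, tissue) == pytest.approx(1.0)

    def test_b0_is_pure_relaxation_mixture(self, tissue):
        te = 54.0
        theta = fold_angle_deg(np.array(tissue.n), np.array([0.0, 0, 1]))
        expected = tissue.f * np.exp(-12.0 * te * 1e-3) + (1 - tissue.f) * np.exp(
            -relaxation_rate(tissue.relax_extra, theta) * te * 1e-3
        )
        assert signal_no_dispersion(0.0, [0, 0, 1], te, tissue) == pytest.approx(expected)

    def test_single_compartment_closed_form(self, tissue):
        s = signal_no_dispersion(1500.0, [0, 0, 1], 0.0, tissue.with_(f=1.0))
        assert s == pytest.approx(np.exp(-1.5 * 2.6), rel=1e-12)

    def test_strictly_decreasing_in_b_and_te(self, tissue):
        g = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        b = np.array([0.0, 500.0, 1000.0, 1500.0])
        s_b = signal_no_dispersion(b, g, 54.0, tissue)
        assert np.all(np.diff(s_b) < 0)
        te = np.array([0.0, 30.0, 60.0, 120.0])
        s_te = signal_no_dispersion(750.0, g, te, tissue)
        assert np.all(np.diff(s_te) < 0)


class TestAdcAnalytic:
    def test_unweighted_mean_at_te_zero(self, tissue):
        assert adc_analytic(0.0, 0.0, "parallel", tissue.with_(f=0.5)) == pytest.approx(2.3)

    def test_single_compartment_limits(self, tissue):
        assert adc_analytic(80.0, 30.0, "parallel", tissue.with_(f=1.0)) == pytest.approx(2.6)
        assert adc_analytic(80.0, 30.0, "perpendicular", tissue.with_(f=0.0)) == pytest.approx(0.4)

    @pytest.mark.parametrize("theta", [0.0, 30.0, 54.7, 90.0])
    @pytest.mark.parametrize("mode", ["parallel", "perpendicular"])
    def test_matches_low_b_slope_of_signal(self, tissue, theta, mode):
        """ADC must equal -d ln S / d b at b = 0 (central differences, step
        1 s/mm^2; the closed-form signal extends smoothly to negative b)."""
        te = 54.0
        n = np.array([np.sin(np.radians(theta)), 0.0, np.cos(np.radians(theta))])
        tis = tissue.with_(n=tuple(n / np.linalg.norm(n)))
        if mode == "parallel":
            g = np.array(tis.n)
        else:
            g = np.array([np.cos(np.radians(theta)), 0.0, -np.sin(np.radians(theta))])
        db = 1.0
        s_lo = signal_no_dispersion(-db, g, te, tis)
        s_hi = signal_no_dispersion(db, g, te, tis)
        slope = -(np.log(s_hi) - np.log(s_lo)) / (2 * db) * 1e3
        assert adc_analytic(te, theta, mode, tis) == pytest.approx(slope, abs=1e-6)

    def test_theta_independent_at_te_zero(self, tissue):
        vals = [adc_analytic(0.0, th, "parallel", tissue) for th in (0, 30, 60, 90)]
        assert np.ptp(vals) < 1e-12


class TestAnalyticMeasures:
    def test_stick_only_has_unit_fa(self, tissue):
        m = analytic_dt_measures(54.0, 20.0, tissue.with_(f=1.0))
        assert m.rd == pytest.approx(0.0)
        assert m.fa == pytest.approx(1.0)

    def test_zeppelin_only_closed_form(self, tissue):
        """FA of eigenvalues (2, 0.4, 0.4) via the independent pairwise formula."""
        m = analytic_dt_measures(0.0, 0.0, tissue.with_(f=0.0))
        l1, l2, l3 = 2.0, 0.4, 0.4
        fa_oracle = np.sqrt(
            0.5 * ((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2)
            / (l1**2 + l2**2 + l3**2)
        )
        assert m.md == pytest.approx(0.9333333333, abs=1e-9)
        assert m.fa == pytest.approx(fa_oracle, abs=1e-12)

    def test_md_identity_and_fa_range(self, tissue):
        for te in (0.0, 54.0, 130.0):
            for th in (0.0, 45.0, 90.0):
                m = analytic_dt_measures(te, th, tissue)
                assert m.md == pytest.approx((m.ad + 2 * m.rd) / 3, abs=1e-12)
                assert 0.0 <= m.fa <= 1.0

    def test_orientation_dependence_signs(self, tissue):
        """AD rises and RD falls from theta 0 to 90 under the sin^4 extra-axonal rate."""
        m0 = analytic_dt_measures(54.0, 0.0, tissue)
        m90 = analytic_dt_measures(54.0, 90.0, tissue)
        assert m90.ad > m0.ad
        assert m90.rd < m0.rd
        assert m90.fa > m0.fa


class TestWatsonDispersion:
    def test_concentration_limit_matches_coherent(self, tissue):
        for g in (np.array([1.0, 0, 0]), np.array([0, 0, 1.0])):
            s0 = signal_no_dispersion(1500.0, g, 54.0, tissue)
            s1 = signal_with_dispersion(1500.0, g, 54.0, tissue.with_(kappa=1e6))
            assert abs(s1 - s0) < 1e-4

    def test_uniform_limit_rotation_invariant(self, tissue):
        g = np.array([1.0, 0, 0])
        axes = [(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), tuple(np.ones(3) / np.sqrt(3))]
        vals = [
            signal_with_dispersion(1500.0, g, 54.0, tissue.with_(kappa=0.0, n=ax))
            for ax in axes
        ]
        assert np.ptp(vals) < 1e-6

    def test_monotone_convergence_with_kappa(self, tissue):
        g = np.array([1.0, 0, 0])
        s_coh = signal_no_dispersion(1500.0, g, 54.0, tissue)
        gaps = [
            abs(signal_with_dispersion(1500.0, g, 54.0, tissue.with_(kappa=float(k))) - s_coh)
            for k in (1.0, 4.0, 16.0, 64.0, 256.0)
        ]
        assert np.all(np.diff(gaps) < 0)

    def test_matches_monte_carlo_at_kappa16(self, tissue, rng):
        """Quadrature vs rejection-sampled Watson average (2e5 draws, 3 SE)."""
        kappa = 16.0
        samples = []
        total = 0
        while total < 200_000:
            v = rng.normal(size=(200_000, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            keep = rng.uniform(size=len(v)) < np.exp(kappa * (v[:, 2] ** 2 - 1.0))
            samples.append(v[keep])
            total += keep.sum()
        v = np.vstack(samples)[:200_000]
        g = np.array([1.0, 0.0, 0.0])
        b0 = np.array([0.0, 0.0, 1.0])
        c2 = (v @ g) ** 2
        theta = np.degrees(np.arccos(np.abs(v @ b0)))
        d_ia = c2 * tissue.d_ia_par
        d_ea = tissue.d_ea_perp + c2 * (tissue.d_ea_par - tissue.d_ea_perp)
        r2_ea = relaxation_rate(tissue.relax_extra, theta)
        s = tissue.f * np.exp(-12.0 * 0.054 - 1.5 * d_ia) + (1 - tissue.f) * np.exp(
            -r2_ea * 0.054 - 1.5 * d_ea
        )
        mc, se = s.mean(), s.std() / np.sqrt(len(s))
        q = signal_with_dispersion(1500.0, g, 54.0, tissue.with_(kappa=kappa))
        assert abs(q - mc) < 3 * se

    def test_node_count_floor(self, tissue):
        with pytest.raises(ValueError):
            watson_quadrature(np.array([0.0, 0, 1.0]), 16.0, n_polar=4)

    def test_quadrature_weights_normalised(self):
        _, w = watson_quadrature(np.array([0.0, 0, 1.0]), 16.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestOdKappa:
    def test_round_trip(self):
        for kappa in (0.5, 4.0, 16.0, 64.0):
            assert od_to_kappa(kappa_to_od(kappa)) == pytest.approx(kappa, rel=1e-10)

    def test_od_in_unit_interval(self):
        assert 0 < kappa_to_od(16.0) < 1


class TestTissueValidation:
    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            TissueParams(f=1.5)

    def test_rejects_oblate_zeppelin(self):
        with pytest.raises(ValueError):
            TissueParams(d_ea_par=0.4, d_ea_perp=2.0)

    def test_rejects_non_unit_fibre(self):
        with pytest.raises(ValueError):
            TissueParams(n=(1.0, 1.0, 0.0))
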