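"""Match point, Stuhrmann, parallel-axis and composite-function analysis."""

import numpy as np
import pytest

import sasreport as sr
from sasreport.contrast_series import ContrastError


def _point(f, i0, s_i0, c):
    g = sr.GuinierResult(I0=i0, sigma_I0=s_i0, Rg=25.0, sigma_Rg=0.5,
                         first_point=1, last_point=20, qRg_min=0.9,
                         qRg_max=1.3, pearson_r=-0.99)
    return sr.ContrastPoint(f_d2o=f, c=c, guinier=g)


class TestMatchPointExperimental:
    def test_printed_sans_series_gives_51(self, printed_i0_series):
        res = sr.match_point_experimental(printed_i0_series)
        assert res.match_point_pct == pytest.approx(51.0, abs=1.0)
        assert not res.extrapolated

    def test_two_point_symmetry(self):
        pts = [_point(0.0, 1.0, 0.01, 1.0), _point(1.0, 1.0, 0.01, 1.0)]
        res = sr.match_point_experimental(sr.ContrastSeries(pts))
        assert res.match_point_pct == pytest.approx(50.0, rel=1e-9)

    def test_exact_affine_series_root(self):
        a, b = 0.8, 1.6  # y = a - b f, root at 0.5
        pts = []
        for f in (0.0, 0.1, 0.3, 0.7, 0.9):
            y = a - b * f
            pts.append(_point(f, y**2, 1e-6, 1.0))
        res = sr.match_point_experimental(sr.ContrastSeries(pts))
        assert res.match_point_pct == pytest.approx(100 * a / b, rel=1e-6)

    def test_one_sided_series_flagged_extrapolated(self):
        pts = [_point(f, (1.0 - 0.5 * f) ** 2, 1e-3, 1.0)
               for f in (0.0, 0.2, 0.4, 0.6)]
        res = sr.match_point_experimental(sr.ContrastSeries(pts))
        assert res.extrapolated
        assert res.match_point_pct == pytest.approx(200.0, rel=0.01)

    def test_duplicate_fractions_rejected(self):
        with pytest.raises(ContrastError, match="distinct"):
            sr.ContrastSeries([_point(0.1, 1, 0.01, 1), _point(0.1, 2, 0.01, 1)])


@pytest.fixture
def two_body_series():
    spec = sr.BodySpec("two_sphere", (20.0, 10.0), 30.0, (3.0e10, 6.5e10))
    return spec, sr.simulate_cv_series(spec, [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


def _stuhrmann_axes(spec, series):
    V = spec.volumes()
    x, y = [], []
    for (d1, d2), rg in zip(series.truth.contrasts,
                            series.truth.rg_by_condition):
        dbar = (d1 * V[0] + d2 * V[1]) / (V[0] + V[1])
        x.append(1.0 / dbar)
        y.append(np.sign(rg) * rg**2)
    return np.array(x), np.array(y)


class TestStuhrmann:
    def test_homogeneous_particle_flat(self):
        spec = sr.BodySpec("two_sphere", (20.0, 10.0), 30.0, (3.0e10, 3.0e10))
        series = sr.simulate_cv_series(spec, [0.0, 0.1, 0.2, 0.3])
        x, y = _stuhrmann_axes(spec, series)
        res = sr.stuhrmann_fit(x, y)
        rg = np.sqrt(y[0])
        scale_alpha = rg**2 / abs(x).max()
        assert res.Rm == pytest.approx(rg, rel=1e-6)
        assert abs(res.alpha) < 1e-6 * scale_alpha
        assert abs(res.beta) < 1e-6 * scale_alpha / abs(x).max()

    def test_two_body_recovery_exact(self, two_body_series):
        spec, series = two_body_series
        x, y = _stuhrmann_axes(spec, series)
        res = sr.stuhrmann_fit(x, y)
        V = spec.volumes()
        f1 = V[0] / sum(V)
        rm2 = f1 * 240.0 + (1 - f1) * 60.0 + f1 * (1 - f1) * 900.0
        assert res.Rm**2 == pytest.approx(rm2, rel=1e-6)

    def test_concentric_spheres_sign_of_alpha(self):
        """Concentric two-phase sphere: beta = 0; alpha > 0 when the
        higher-SLD phase lies further from the center."""
        for inner_sld, outer_sld in ((2e10, 6e10), (6e10, 2e10)):
            spec = sr.BodySpec("two_sphere", (25.0, 12.0), 0.0,
                               (outer_sld, inner_sld))
            series = sr.simulate_cv_series(spec, [0.0, 0.15, 0.3, 0.45])
            x, y = _stuhrmann_axes(spec, series)
            res = sr.stuhrmann_fit(x, y)
            # beta's contribution to Rg^2 is negligible when centers coincide
            assert abs(res.beta) * max(np.abs(x)) ** 2 < 1e-6 * res.Rm**2
            if outer_sld > inner_sld:
                assert res.alpha > 0
            else:
                assert res.alpha < 0

    def test_too_few_points(self):
        with pytest.raises(ContrastError):
            sr.stuhrmann_fit([1e-10, 2e-10], [600, 620])


class TestParallelAxis:
    def test_degenerate_single_size(self):
        f1 = np.array([0.2, 0.5, 0.8])
        rg2 = np.full(3, 240.0)  # R1 = R2, D = 0
        res = sr.parallel_axis(f1, rg2)
        assert res.R1**2 == pytest.approx(240.0, rel=1e-9)
        assert res.R2**2 == pytest.approx(240.0, rel=1e-9)
        assert abs(res.D) ** 2 < 1e-6

    def test_hand_arithmetic_case(self):
        """R1^2=240, R2^2=60, D^2=900: at f1=0.5 Rg^2 = 120+30+225 = 375."""
        f1 = np.array([0.25, 0.5, 0.75])
        rg2 = f1 * 240 + (1 - f1) * 60 + f1 * (1 - f1) * 900
        assert rg2[1] == pytest.approx(375.0)
        res = sr.parallel_axis(f1, rg2)
        assert res.R1 == pytest.approx(np.sqrt(240), rel=1e-9)
        assert res.R2 == pytest.approx(np.sqrt(60), rel=1e-9)
        assert res.D == pytest.approx(30.0, rel=1e-9)

    def test_noisy_recovery_median_within_5pct(self):
        """1% noise on Rg, 7 contrasts, 100 seeds: median recovered
        R1, R2, D within 5% of truth."""
        f1 = np.linspace(0.15, 0.95, 7)
        rg2_true = f1 * 240 + (1 - f1) * 60 + f1 * (1 - f1) * 900
        rg_true = np.sqrt(rg2_true)
        results = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            rg_noisy = rg_true * (1 + 0.01 * rng.standard_normal(7))
            sigma_rg2 = 2 * rg_noisy * (0.01 * rg_noisy)
            res = sr.parallel_axis(f1, rg_noisy**2, sigma_rg2)
            results.append((res.R1, res.R2, res.D))
        med = np.median(np.array(results), axis=0)
        truth = (np.sqrt(240), np.sqrt(60), 30.0)
        for got, want in zip(med, truth):
            assert got == pytest.approx(want, rel=0.05)

    def test_singular_design_reports_leverage(self):
        with pytest.raises(ContrastError, match="leverage"):
            sr.parallel_axis([0.5, 0.5, 0.5], [375, 375, 375])


class TestCompositeFunctions:
    def _series(self, spec, series):
        pts = []
        for f, prof, (d1, d2) in zip(series.f_d2o, series.profiles,
                                     series.truth.contrasts):
            pts.append(sr.ContrastPoint(f_d2o=f, profile=prof,
                                        delta_rho_components=(d1, d2)))
        return sr.ContrastSeries(pts)

    def test_noiseless_recovery(self, two_body_series):
        spec, series = two_body_series
        comp = sr.composite_functions(self._series(spec, series))
        truth = series.truth.components
        for name in ("I11", "I12", "I22"):
            got = getattr(comp, name)
            want = truth[name]
            assert np.max(np.abs(got - want)) <= 1e-3 * np.max(np.abs(want))
        np.testing.assert_allclose(comp.I_homogeneous,
                                   comp.I11 + comp.I12 + comp.I22)

    def test_q0_coherence_identity(self, two_body_series):
        spec, series = two_body_series
        comp = sr.composite_functions(self._series(spec, series))
        assert comp.I12[0] ** 2 == pytest.approx(
            4 * comp.I11[0] * comp.I22[0], rel=1e-6)

    def test_component_at_match_leaves_single_term(self):
        spec = sr.BodySpec("two_sphere", (20.0, 10.0), 30.0, (3.0e10, 5.5e10))
        series = sr.simulate_cv_series(spec, [0.0, 0.3, 0.6, 1.0])
        # condition where body 2 is exactly matched
        rho2 = 5.5e10
        lo = sr.solvent_sld(sr.SolventSpec(0.0))
        hi = sr.solvent_sld(sr.SolventSpec(1.0))
        f_match = (rho2 - lo) / (hi - lo)
        one = sr.simulate_cv_series(spec, [f_match])
        d1, d2 = one.truth.contrasts[0]
        assert abs(d2) < 1e-4 * abs(d1)
        comp = sr.composite_functions(self._series(spec, series))
        expected = d1**2 * comp.I11
        np.testing.assert_allclose(one.profiles[0].I, expected, rtol=1e-6)

    def test_rank_deficient_contrasts_rejected(self):
        spec = sr.BodySpec("two_sphere", (20.0, 10.0), 30.0, (3.0e10, 6.5e10))
        series = sr.simulate_cv_series(spec, [0.0, 0.2, 0.4])
        pts = []
        for f, prof in zip(series.f_d2o, series.profiles):
            pts.append(sr.ContrastPoint(f_d2o=f, profile=prof,
                                        delta_rho_components=(1e10, 1e10)))
        with pytest.raises(ContrastError, match="rank"):
            sr.composite_functions(sr.ContrastSeries(pts))


class TestCrossConsistency:
    def test_stuhrmann_vs_parallel_axis_at_infinite_contrast(self, two_body_series):
        spec, series = two_body_series
        x, y = _stuhrmann_axes(spec, series)
        st = sr.stuhrmann_fit(x, y)
        V = spec.volumes()
        f1_inf = V[0] / sum(V)
        f1_pts, rg2_pts = [], []
        for (d1, d2), rg in zip(series.truth.contrasts,
                                series.truth.rg_by_condition):
            f1_pts.append(sr.contrast_fractions((d1, d2), V)[0])
            rg2_pts.append(np.sign(rg) * rg**2)
        pa = sr.parallel_axis(np.array(f1_pts), np.array(rg2_pts))
        rm2_pa = (f1_inf * pa.R1**2 + (1 - f1_inf) * pa.R2**2
                  + f1_inf * (1 - f1_inf) * pa.D**2)
        assert st.Rm**2 == pytest.approx(rm2_pa, rel=0.01)

    def test_simulated_match_point_vs_calculated(self):
        """Experimental match point from a simulated series built from a
        composition agrees with the calculated one within 2 points."""
        kinase = sr.Component("kinase", "protein", "MKTAYIAKQRQISFVKSHFSRQ" * 8)
        inhibitor = sr.Component("inhibitor", "protein", "GSDEFLKAHEKLMNDVWQ" * 3,
                                 nonexchangeable_deuteration=0.86)
        assembly = sr.Assembly([kinase, inhibitor])
        calc = sr.match_point_calculated(assembly)
        series = sr.simulate_cv_series(
            assembly, [0.0, 0.1, 0.2, 0.4, 0.8, 0.9, 1.0],
            concentration=11.9,
            noise=sr.NoiseSpec(relative_level=0.01, sigma_floor=0.0, seed=5))
        pts = []
        for f, prof in zip(series.f_d2o, series.profiles):
            g = sr.auto_guinier_range(prof, min_points=5)
            pts.append(sr.ContrastPoint(f_d2o=f, c=11.9, guinier=g))
        res = sr.match_point_experimental(sr.ContrastSeries(pts))
        assert res.match_point_pct == pytest.approx(calc, abs=2.0)
        assert series.truth.match_point_pct == pytest.approx(calc, abs=0.5)
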