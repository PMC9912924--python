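"""Indirect Fourier transform, slit smearing and desmearing."""

import numpy as np
import pytest
from scipy.integrate import quad

import sasreport as sr
from sasreport.pddf import PDDFError

SLIT = sr.BeamGeometry("slit", plateau=0.15, base=0.29)


def sphere_intensity(u, R=30.0, drho=2e10, n=1e12):
    x = u * R
    F = 3 * (np.sin(x) - x * np.cos(x)) / x**3
    V = 4 / 3 * np.pi * R**3 * 1e-24
    return n * (drho * V) ** 2 * F**2


class TestSmear:
    def test_delta_profile_is_identity(self):
        q = np.linspace(0.01, 0.3, 100)
        mc = sr.ModelCurve(q=q, I_model=np.exp(-q * 10))
        out = sr.smear(mc, sr.BeamGeometry("slit", plateau=0.0, base=0.0))
        np.testing.assert_array_equal(out.I_model, mc.I_model)

    def test_constant_intensity_preserved(self):
        q = np.linspace(0.01, 0.3, 100)
        mc = sr.ModelCurve(q=q, I_model=np.full(100, 3.7))
        out = sr.smear(mc, SLIT)
        np.testing.assert_allclose(out.I_model, 3.7, rtol=1e-10)

    def test_matches_direct_quadrature(self):
        """Sphere curve smeared with the trapezoid matches brute-force
        numerical integration to < 0.1%."""
        q = np.linspace(1e-4, 1.2, 3000)
        mc = sr.ModelCurve(q=q, I_model=sphere_intensity(q))
        out = sr.smear(mc, SLIT)

        def W(t):
            return 1.0 if t <= 0.15 else (0.29 - t) / (0.29 - 0.15)

        norm = quad(W, 0, 0.29)[0]
        for i in (50, 500, 1500, 2500):
            brute = quad(lambda t: W(t) * sphere_intensity(
                np.sqrt(q[i] ** 2 + t**2)), 0, 0.29, limit=200)[0] / norm
            assert out.I_model[i] == pytest.approx(brute, rel=1e-3)

    def test_linearity(self):
        q = np.linspace(0.01, 0.5, 200)
        I1 = np.exp(-q * 10)
        I2 = 1.0 / (1 + (q * 30) ** 2)
        s1 = sr.smear(sr.ModelCurve(q=q, I_model=I1), SLIT).I_model
        s2 = sr.smear(sr.ModelCurve(q=q, I_model=I2), SLIT).I_model
        s12 = sr.smear(sr.ModelCurve(q=q, I_model=2 * I1 + 3 * I2), SLIT).I_model
        np.testing.assert_allclose(s12, 2 * s1 + 3 * s2, rtol=1e-9)


class TestIFT:
    def test_noiseless_sphere_closed_form(self):
        q = np.linspace(2e-3, 0.25, 300)
        prof = sr.sphere_profile(30.0, 2e10, 1e12, q_grid=q)
        res = sr.ift(prof, 60.0, alpha="auto")
        p_true = sr.sphere_pddf(res.r, 30.0)
        p_norm = res.p / np.trapezoid(res.p, res.r)
        rms = np.sqrt(np.mean((p_norm - p_true) ** 2)) / p_true.max()
        assert rms < 0.01
        assert res.Rg**2 == pytest.approx(3.0 * 30.0**2 / 5.0, rel=0.005)
        assert res.p[0] == 0.0 and res.p[-1] == 0.0

    def test_i0_moment_matches_forward_scattering(self):
        q = np.linspace(2e-3, 0.25, 300)
        prof = sr.sphere_profile(30.0, 2e10, 1e12, q_grid=q)
        res = sr.ift(prof, 60.0, alpha="auto")
        I_q0 = 1e12 * (2e10 * 4 / 3 * np.pi * 30**3 * 1e-24) ** 2
        assert res.I0 == pytest.approx(I_q0, rel=0.01)

    def test_noisy_sphere_recovery(self):
        q = np.linspace(2e-3, 0.25, 300)
        noise = sr.NoiseSpec(relative_level=0.01, sigma_floor=0.0, seed=42)
        prof = sr.sphere_profile(30.0, 2e10, 1e12, q_grid=q, noise=noise)
        res = sr.ift(prof, 60.0, alpha="auto")
        assert res.Rg == pytest.approx(23.24, rel=0.02)
        assert 0.5 <= res.chi2 <= 2.0
        assert 0.0 < res.cormap_p <= 1.0

    def test_guinier_pddf_consistency_on_ideal_data(self):
        # ideal (noise-free) intensities with realistic 1% uncertainties
        q = np.linspace(2e-3, 0.25, 300)
        p = sr.sphere_profile(30.0, 2e10, 1e12, q_grid=q)
        prof = sr.SASProfile(q=p.q, I=p.I, sigma=p.I * 0.01 + 1e-16)
        g = sr.auto_guinier_range(prof)
        res = sr.ift(prof, 60.0, alpha="auto")
        assert abs(res.Rg - g.Rg) / g.Rg < 0.02
        assert abs(res.I0 - g.I0) / g.I0 < 0.01

    def test_invalid_dmax(self):
        q = np.linspace(2e-3, 0.25, 50)
        prof = sr.sphere_profile(30.0, 2e10, 1e12, q_grid=q)
        with pytest.raises(PDDFError):
            sr.ift(prof, -5.0)


class TestDesmear:
    def test_point_geometry_identity(self, sphere30):
        res = sr.ift(sphere30, 60.0, alpha=1e-6)
        out = sr.desmear(sphere30, res, sr.BeamGeometry())
        assert out is sphere30

    def test_closed_loop_recovers_truth(self):
        """smear(truth) fitted with the slit kernel, then desmeared,
        reproduces the unsmeared curve to < 0.5%."""
        qfine = np.linspace(1e-4, 1.2, 3000)
        truth_fine = sphere_intensity(qfine)
        smeared_fine = sr.smear(sr.ModelCurve(q=qfine, I_model=truth_fine), SLIT)
        q = np.linspace(5e-3, 0.25, 250)
        I_s = np.interp(q, qfine, smeared_fine.I_model)
        prof = sr.SASProfile(q=q, I=I_s, sigma=I_s * 1e-3 + 1e-16)
        res = sr.ift(prof, 60.0, alpha="auto", beam=SLIT)
        desm = sr.desmear(prof, res, SLIT)
        truth = sphere_intensity(q)
        assert np.max(np.abs(desm.I - truth) / truth.max()) < 0.005

    def test_desmearing_deepens_first_minimum(self):
        qfine = np.linspace(1e-4, 1.2, 3000)
        truth_fine = sphere_intensity(qfine)
        smeared_fine = sr.smear(sr.ModelCurve(q=qfine, I_model=truth_fine), SLIT)
        q = np.linspace(5e-3, 0.25, 250)
        I_s = np.interp(q, qfine, smeared_fine.I_model)
        prof = sr.SASProfile(q=q, I=I_s, sigma=I_s * 1e-3 + 1e-16)
        res = sr.ift(prof, 60.0, alpha="auto", beam=SLIT)
        desm = sr.desmear(prof, res, SLIT)
        band = (q > 0.13) & (q < 0.17)  # around the first minimum at qR=4.493
        assert desm.I[band].min() < prof.I[band].min()


class TestScanDmax:
    def test_sphere_dmax_recovered(self):
        q = np.linspace(2e-3, 0.25, 250)
        prof = sr.sphere_profile(30.0, 2e10, 1e12, q_grid=q)
        res = sr.scan_dmax(prof, np.arange(40.0, 95.0, 5.0), alpha="auto")
        assert abs(res.d_max - 60.0) <= 5.0

    def test_single_candidate_returned(self, sphere30):
        res = sr.scan_dmax(sphere30.window(q_max=0.25), [60.0], alpha=1e-5)
        assert res.d_max == 60.0

    def test_pure_noise_flagged_unstable(self):
        rng = np.random.default_rng(11)
        q = np.linspace(0.01, 0.3, 150)
        I = rng.normal(0.0, 1.0, 150)
        prof = sr.SASProfile(q=q, I=I, sigma=np.ones(150))
        res = sr.scan_dmax(prof, [40.0, 60.0, 80.0, 100.0], alpha=1e-2,
                           nonneg=False)
        assert any("unstable" in w for w in res.warnings)
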