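"""Table assembly, validation rules and figure series."""

import numpy as np
import pytest

import sasreport as sr


def _guinier(I0=0.12, sI0=0.002, rg=25.4, srg=0.7, qmax=1.27):
    return sr.GuinierResult(I0=I0, sigma_I0=sI0, Rg=rg, sigma_Rg=srg,
                            first_point=1, last_point=31, qRg_min=0.25,
                            qRg_max=qmax, pearson_r=-0.99, fidelity=0.99)


def _pddf(I0=0.114, sI0=0.001, rg=26.15, srg=0.06):
    return sr.PDDFResult(
        r=np.linspace(0, 92, 11), p=np.zeros(11), d_max=92.0, alpha=1.0,
        I0=I0, sigma_I0=sI0, Rg=rg, sigma_Rg=srg,
        fit_q_range=(0.010, 0.372), chi2=1.12, cormap_p=0.85)


class TestValidate:
    def test_dna_example_rg_agreement_passes(self):
        """Guinier 25.4 +/- 0.7 vs P(r) 26.15 +/- 0.06: |d| = 0.75 is
        within 2 * combined sigma = 1.41, so no R1 flag."""
        flags = sr.validate(guinier=_guinier(), pddf=_pddf())
        assert not [f for f in flags if f.rule == "R1"]

    def test_discrepant_rg_flagged(self):
        flags = sr.validate(guinier=_guinier(rg=20.0, srg=0.1), pddf=_pddf())
        assert [f for f in flags if f.rule == "R1" and f.severity == "warn"]

    def test_identical_results_zero_flags(self):
        g = _guinier()
        p = _pddf(I0=g.I0, rg=g.Rg, srg=g.sigma_Rg)
        assert sr.validate(guinier=g, pddf=p) == []

    def test_vp_over_m_protein_band(self):
        size = sr.SizeReport(Vp=53000.0, M_expected=34389.0,
                             Vp_over_M=53000.0 / 34389.0)
        flags = sr.validate(size=size, kind="protein")
        assert not [f for f in flags if f.rule == "R4"]
        flags_na = sr.validate(size=size, kind="dna")
        assert [f for f in flags_na if f.rule == "R4"]  # 1.54 > 1.4 band

    def test_mass_ratio_rules(self):
        for ratio, severity in ((1.05, None), (1.15, "info"), (1.40, "warn")):
            size = sr.SizeReport(ratio_to_expected=ratio)
            flags = [f for f in sr.validate(size=size) if f.rule == "R5"]
            if severity is None:
                assert flags == []
            else:
                assert flags[0].severity == severity

    def test_cormap_and_chi2_rules(self):
        class Fit:
            label = "model"
            cormap_p = 5e-5
            chi2 = 2.6
            run_interval = (0.1, 0.18)
        flags = sr.validate(fits=[Fit()])
        rules = {f.rule for f in flags}
        assert {"R6", "R7"} <= rules
        r6 = next(f for f in flags if f.rule == "R6")
        assert "0.1" in r6.message and "0.18" in r6.message

    def test_purity(self):
        g, p = _guinier(rg=20.0, srg=0.1), _pddf()
        f1 = sr.validate(guinier=g, pddf=p)
        f2 = sr.validate(guinier=g, pddf=p)
        assert [vars(a) for a in f1] == [vars(b) for b in f2]


class TestBuildAndRender:
    def _table(self):
        size = sr.SizeReport(Vp=21100.0, M_expected=16632.0, Vp_over_M=1.27,
                             M_from_I0c=15000.0, ratio_to_expected=0.90,
                             M_conc_independent=16000.0,
                             conc_independent_method="volume of correlation")
        return sr.build_table(
            "general",
            sample_rows=[("Organism", "Human"), ("Source", "synthetic oligomers")],
            guinier=_guinier(), pddf=_pddf(), size=size,
            deposition_rows=[("SASBDB ID", "SASDCB3")])

    def test_general_panels_present(self):
        table = self._table()
        assert list(table.panels) == ["a", "b", "c", "d", "e", "f"]
        labels = [r.label for r in table.panels["c"]]
        assert any("Guinier" in l for l in labels)
        assert any("P(r)" in l for l in labels)

    def test_no_computed_result_dropped(self):
        table = self._table()
        n_rows = sum(len(rows) for rows in table.panels.values())
        # 2 user sample rows + 10 panel-c rows (5 Guinier incl. fidelity and
        # Pearson R + 5 P(r)) + 4 panel-d rows + 1 deposition row
        assert n_rows == 17

    def test_missing_concentration_renders_nd(self):
        size = sr.SizeReport(Vp=21100.0, M_expected=16632.0)
        table = sr.build_table("general", size=size)
        d_rows = {r.label: r.value for r in table.panels["d"]}
        assert d_rows["M from I(0)/c"] == "n.d."
        assert any(f.rule == "n.d." for f in table.flags)

    def test_cv_variant_requires_three_conditions(self):
        with pytest.raises(ValueError, match=">= 3"):
            sr.build_table("sas_cv", contrast_rows=[("x", 1), ("y", 2)])

    def test_cv_variant_panel_f_rows(self):
        table = sr.build_table(
            "sas_cv",
            contrast_rows=[("c1", "a"), ("c2", "b"), ("c3", "c")],
            component_rows=[("Stuhrmann plot", "25.90 / 24.81 / 26.43"),
                            ("Parallel axis theorem", "26.04 / 25.10 / 25.60"),
                            ("Composite scattering functions", "25.6 / 24.9")])
        labels = [r.label for r in table.panels["f"]]
        assert labels == ["Stuhrmann plot", "Parallel axis theorem",
                          "Composite scattering functions"]
        assert "g" in table.panels

    def test_markdown_sections_in_order(self):
        text = sr.render(self._table(), "markdown")
        positions = [text.index(f"## Panel ({p})") for p in "abcdef"]
        assert positions == sorted(positions)

    def test_csv_flat_rows(self):
        text = sr.render(self._table(), "csv")
        lines = text.strip().splitlines()
        assert lines[0] == "panel,label,value,units,provenance"
        assert any(line.startswith("a,Organism,Human") for line in lines)

    def test_json_round_trip(self):
        table = self._table()
        back = sr.parse_json(sr.render(table, "json"))
        assert back.variant == table.variant
        for panel in table.panels:
            got = [(r.label, r.value, r.units, r.provenance)
                   for r in back.panels[panel]]
            want = [(r.label, r.value, r.units, r.provenance)
                    for r in table.panels[panel]]
            assert got == want

    def test_unknown_format_rejected(self):
        with pytest.raises(ValueError, match="format"):
            sr.render(self._table(), "docx")


class TestFigureSeries:
    def test_kratky_peak_of_ideal_guinier(self):
        """(qRg)^2 I/I0 for pure Guinier decay peaks at x = sqrt(3),
        y = 3/e."""
        q = np.linspace(1e-3, 0.2, 4000)
        rg = 30.0
        I = 100.0 * np.exp(-(q * rg) ** 2 / 3.0)
        prof = sr.SASProfile(q=q, I=I)
        g = _guinier(I0=100.0, rg=rg)
        series = sr.figure_series(profile=prof, guinier=g)
        x, y = series["kratky_dimensionless"]
        i_peak = np.argmax(y)
        assert x[i_peak] == pytest.approx(np.sqrt(3.0), abs=0.01)
        assert y[i_peak] == pytest.approx(3.0 / np.e, rel=1e-3)

    def test_pddf_and_residual_passthrough(self):
        p = _pddf()

        class Fit:
            q = np.linspace(0.01, 0.3, 10)
            residuals = np.ones(10)
        series = sr.figure_series(pddf=p, fits=[Fit()])
        np.testing.assert_array_equal(series["pddf"][0], p.r)
        np.testing.assert_array_equal(series["residuals"][0][1], np.ones(10))
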