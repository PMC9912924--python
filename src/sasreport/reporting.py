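"""Assembly, validation and rendering of the SAS reporting tables.

Two table variants are supported: the *general* table (panels a-f: sample
details, data collection, structural parameters, particle size, modelling,
deposition) and the *contrast-variation* table (panels a-g, adding solvent
match points per condition and a component-structural-parameters panel).

``validate`` encodes the cross-checks a careful reader applies to such a
table as explicit, stable rules (R1-R7 below).  The thresholds quantify
deliberately qualitative reporting language ("reasonable agreement",
"acceptable range") and every one of them is overridable.
"""

from __future__ import annotations

import csv
import io as _io
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .guinier import GuinierResult
from .pddf import PDDFResult


@dataclass
class ValidationFlag:
    rule: str
    severity: str                    # info | warn | fail
    message: str
    values: dict = field(default_factory=dict)


@dataclass
class Row:
    label: str
    value: object
    units: str = ""
    provenance: str = "computed"     # computed | user | external-tool
    software: str = ""


@dataclass
class TemplateTable:
    variant: str                     # "general" | "sas_cv"
    panels: dict                     # panel id -> list[Row]
    flags: list = field(default_factory=list)

    PANELS = {
        "general": ["a", "b", "c", "d", "e", "f"],
        "sas_cv": ["a", "b", "c", "d", "e", "f", "g"],
    }


# default rule thresholds; every key can be overridden via ``tolerances``
DEFAULT_TOLERANCES = {
    "rg_agreement_nsigma": 2.0,      # R1
    "i0_agreement_rel": 0.05,        # R2
    "qrg_max": 1.3,                  # R3
    "vp_over_m_protein": (1.1, 1.8), # R4, A^3/Da
    "vp_over_m_nucleic": (1.1, 1.4),
    "mass_ratio_warn": 0.25,         # R5
    "mass_ratio_info": 0.10,
    "cormap_p_min": 0.01,            # R6
    "chi2_band": (0.5, 2.0),         # R7
}


def validate(guinier: GuinierResult | None = None,
             pddf: PDDFResult | None = None,
             size=None, fits=None, kind: str = "protein",
             tolerances: dict | None = None) -> list:
    """Apply the documented consistency rules and return flags.

    Pure function: identical inputs always produce identical flags.

    R1  Guinier and P(r) Rg agree within n sigma (combined).
    R2  Guinier and P(r) I(0) agree within a relative tolerance.
    R3  qRg_max of the Guinier window within the configured limit.
    R4  V_P / M within the hydrated-particle band for the molecule class.
    R5  M from I(0)/c within 25% (warn) / 10% (info) of composition M.
    R6  CorMap P-value of any model fit above the significance floor.
    R7  Reduced chi^2 of any model fit inside the plausibility band.
    """
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    flags: list[ValidationFlag] = []
    if guinier is not None and pddf is not None:
        d = abs(guinier.Rg - pddf.Rg)
        comb = math.hypot(guinier.sigma_Rg, pddf.sigma_Rg)
        limit = tol["rg_agreement_nsigma"] * comb
        if comb > 0 and d > limit:
            flags.append(ValidationFlag(
                "R1", "warn",
                f"Guinier Rg {guinier.Rg:.2f} and P(r) Rg {pddf.Rg:.2f} A "
                f"differ by {d:.2f} A (> {limit:.2f})",
                {"rg_guinier": guinier.Rg, "rg_pddf": pddf.Rg}))
        rel = abs(guinier.I0 - pddf.I0) / max(abs(guinier.I0), 1e-300)
        if rel > tol["i0_agreement_rel"]:
            flags.append(ValidationFlag(
                "R2", "warn",
                f"Guinier I(0) and P(r) I(0) differ by {100 * rel:.1f}%",
                {"i0_guinier": guinier.I0, "i0_pddf": pddf.I0}))
    if guinier is not None and guinier.qRg_max > tol["qrg_max"]:
        flags.append(ValidationFlag(
            "R3", "info",
            f"Guinier window extends to qRg = {guinier.qRg_max:.2f} "
            f"(> {tol['qrg_max']})",
            {"qrg_max": guinier.qRg_max}))
    if size is not None and size.Vp_over_M is not None:
        lo, hi = (tol["vp_over_m_nucleic"] if kind in ("dna", "rna")
                  else tol["vp_over_m_protein"])
        v = size.Vp_over_M
        if not lo <= v <= hi:
            flags.append(ValidationFlag(
                "R4", "warn",
                f"V_P/M = {v:.2f} A^3/Da outside the hydrated-{kind} band "
                f"[{lo}, {hi}]", {"vp_over_m": v}))
    if size is not None and size.ratio_to_expected is not None:
        dev = abs(size.ratio_to_expected - 1.0)
        if dev > tol["mass_ratio_warn"]:
            flags.append(ValidationFlag(
                "R5", "warn",
                f"M from I(0)/c deviates {100 * dev:.0f}% from the "
                "composition mass", {"ratio": size.ratio_to_expected}))
        elif dev > tol["mass_ratio_info"]:
            flags.append(ValidationFlag(
                "R5", "info",
                f"M from I(0)/c deviates {100 * dev:.0f}% from the "
                "composition mass", {"ratio": size.ratio_to_expected}))
    for fit in (fits or []):
        label = getattr(fit, "label", "model fit")
        if fit.cormap_p < tol["cormap_p_min"]:
            lo_q, hi_q = fit.run_interval
            flags.append(ValidationFlag(
                "R6", "warn",
                f"{label}: CorMap P = {fit.cormap_p:.3g} indicates systematic "
                f"misfit over q = {lo_q:.3g}-{hi_q:.3g} A^-1",
                {"cormap_p": fit.cormap_p, "run_interval": [lo_q, hi_q]}))
        lo, hi = tol["chi2_band"]
        if not lo <= fit.chi2 <= hi:
            flags.append(ValidationFlag(
                "R7", "info",
                f"{label}: reduced chi^2 = {fit.chi2:.2f} outside [{lo}, {hi}]",
                {"chi2": fit.chi2}))
    return flags


def _fmt(value, ndigits=4):
    if value is None:
        return "n.d."
    if isinstance(value, float):
        return f"{value:.{ndigits}g}"
    return str(value)


def build_table(variant: str, sample_rows=None, collection_rows=None,
                guinier: GuinierResult | None = None,
                pddf: PDDFResult | None = None,
                size=None, fits=None, contrast_rows=None,
                component_rows=None, deposition_rows=None,
                software: str = "sasreport") -> TemplateTable:
    """Assemble a TemplateTable from computed results and user metadata.

    Computed rows carry provenance "computed" and the producing software
    string; user-supplied rows pass through untouched.  Missing computed
    values are rendered "n.d." and flagged.  The contrast-variation
    variant requires at least 3 contrast conditions.
    """
    if variant not in TemplateTable.PANELS:
        raise ValueError(f"unknown table variant {variant!r}")
    if variant == "sas_cv" and (contrast_rows is None or len(contrast_rows) < 3):
        raise ValueError("contrast-variation table requires >= 3 contrast conditions")
    panels: dict[str, list] = {p: [] for p in TemplateTable.PANELS[variant]}
    flags: list[ValidationFlag] = []

    def user(panel, rows):
        for label, value in (rows or []):
            panels[panel].append(Row(label, value, provenance="user"))

    user("a", sample_rows)
    user("b", collection_rows)
    c = panels["c"]
    if guinier is not None:
        c.append(Row("Guinier I(0) +/- sigma",
                     f"{_fmt(guinier.I0)} +/- {_fmt(guinier.sigma_I0, 2)}",
                     software=software))
        c.append(Row("Guinier Rg +/- sigma (A)",
                     f"{guinier.Rg:.2f} +/- {guinier.sigma_Rg:.2f}",
                     software=software))
        c.append(Row("qRg range (datapoint range)",
                     f"{guinier.qRg_min:.2f}-{guinier.qRg_max:.2f} "
                     f"({guinier.first_point}-{guinier.last_point})",
                     software=software))
        if guinier.fidelity is not None:
            c.append(Row("Linear fit assessment (fidelity)",
                         f"{guinier.fidelity:.2f}", software=software))
        c.append(Row("Pearson's R for fit", f"{guinier.pearson_r:.3f}",
                     software=software))
    if pddf is not None:
        c.append(Row("P(r) I(0) +/- sigma",
                     f"{_fmt(pddf.I0)} +/- {_fmt(pddf.sigma_I0, 2)}",
                     software=software))
        c.append(Row("P(r) Rg +/- sigma (A)",
                     f"{pddf.Rg:.2f} +/- {pddf.sigma_Rg:.2f}",
                     software=software))
        c.append(Row("d_max (A)", f"{pddf.d_max:.0f}", units="A",
                     software=software))
        c.append(Row("P(r) q-range (A^-1)",
                     f"{pddf.fit_q_range[0]:.3g}-{pddf.fit_q_range[1]:.3g}",
                     software=software))
        c.append(Row("P(r) fit: chi^2, CorMap P-value",
                     f"{pddf.chi2:.2f}, {pddf.cormap_p:.2g}",
                     software=software))
    d = panels["d"]
    if size is not None:
        d.append(Row("Porod volume V_P (ratio to M)",
                     f"{_fmt(size.Vp, 5)}"
                     + (f" ({size.Vp_over_M:.2f})" if size.Vp_over_M else ""),
                     units="A^3", software=software))
        if size.M_expected is not None:
            d.append(Row("M from chemical composition",
                         f"{size.M_expected:.0f}", units="Da",
                         software=software))
        if size.M_from_I0c is None:
            d.append(Row("M from I(0)/c", "n.d.", units="Da"))
            flags.append(ValidationFlag(
                "n.d.", "info", "M from I(0)/c not determined "
                "(missing concentration, contrast or absolute scale)"))
        else:
            ratio = (f" ({size.ratio_to_expected:.2f})"
                     if size.ratio_to_expected else "")
            d.append(Row("M from I(0)/c (ratio to expected)",
                         f"{size.M_from_I0c:.0f}{ratio}", units="Da",
                         software=software))
        if size.M_conc_independent is not None:
            d.append(Row(f"M from c-independent method "
                         f"({size.conc_independent_method})",
                         f"{size.M_conc_independent:.0f}", units="Da",
                         software=software))
    e = panels["e"]
    for fit in (fits or []):
        label = getattr(fit, "label", "model fit")
        e.append(Row(f"{label}: chi^2, CorMap P-value",
                     f"{fit.chi2:.2f}, {fit.cormap_p:.2g}",
                     software=software))
    if variant == "sas_cv":
        for label, value in (contrast_rows or []):
            panels["d"].append(Row(label, value, software=software))
        f_panel = panels["f"]
        for label, value in (component_rows or []):
            f_panel.append(Row(label, value, software=software))
        user("g", deposition_rows)
    else:
        user("f", deposition_rows)
    return TemplateTable(variant=variant, panels=panels, flags=flags)


def render(table: TemplateTable, fmt: str = "markdown") -> str:
    """Serialize a table deterministically as markdown, csv or json."""
    if fmt == "markdown":
        out = [f"# SAS reporting table ({table.variant})"]
        for panel in TemplateTable.PANELS[table.variant]:
            out.append(f"\n## Panel ({panel})\n")
            for row in table.panels.get(panel, []):
                unit = f" [{row.units}]" if row.units else ""
                out.append(f"- **{row.label}**{unit}: {row.value}")
        if table.flags:
            out.append("\n## Validation flags\n")
            for fl in table.flags:
                out.append(f"- [{fl.severity}] {fl.rule}: {fl.message}")
        return "\n".join(out) + "\n"
    if fmt == "csv":
        buf = _io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["panel", "label", "value", "units", "provenance"])
        for panel in TemplateTable.PANELS[table.variant]:
            for row in table.panels.get(panel, []):
                writer.writerow([panel, row.label, row.value, row.units,
                                 row.provenance])
        return buf.getvalue()
    if fmt == "json":
        doc = {
            "variant": table.variant,
            "panels": {
                panel: [
                    {"label": r.label, "value": r.value, "units": r.units,
                     "provenance": r.provenance, "software": r.software}
                    for r in table.panels.get(panel, [])
                ]
                for panel in TemplateTable.PANELS[table.variant]
            },
            "flags": [
                {"rule": f.rule, "severity": f.severity, "message": f.message,
                 "values": f.values}
                for f in table.flags
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)
    raise ValueError(f"unknown format {fmt!r}")


def parse_json(text: str) -> TemplateTable:
    """Inverse of ``render(..., fmt='json')``."""
    doc = json.loads(text)
    panels = {
        panel: [Row(r["label"], r["value"], r["units"], r["provenance"],
                    r.get("software", ""))
                for r in rows]
        for panel, rows in doc["panels"].items()
    }
    flags = [ValidationFlag(f["rule"], f["severity"], f["message"],
                            f.get("values", {}))
             for f in doc.get("flags", [])]
    return TemplateTable(variant=doc["variant"], panels=panels, flags=flags)


def figure_series(profile=None, guinier: GuinierResult | None = None,
                  pddf: PDDFResult | None = None, fits=None) -> dict:
    """Data series for the recommended figures.

    * ``log_linear``: (q, I) for the log-linear profile plot.
    * ``kratky_dimensionless``: x = q Rg, y = (q Rg)^2 I / I(0); for ideal
      Guinier decay the peak sits at x = sqrt(3), y = 3/e.
    * ``pddf``: (r, P(r)).
    * ``residuals``: one (q, residual) series per fit.
    """
    series: dict = {}
    if profile is not None:
        series["log_linear"] = (profile.q.copy(), profile.I.copy())
    if profile is not None and guinier is not None:
        x = profile.q * guinier.Rg
        y = x**2 * profile.I / guinier.I0
        series["kratky_dimensionless"] = (x, y)
    if pddf is not None:
        series["pddf"] = (pddf.r.copy(), pddf.p.copy())
    if fits:
        series["residuals"] = [(f.q.copy(), f.residuals.copy()) for f in fits]
    return series
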