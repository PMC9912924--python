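"""Scattering-particle size and mass estimators and their cross-checks.

Three experimental routes are computed and compared with the mass expected
from chemical composition:

* the Porod volume V_P = 2 pi^2 I(0) / Q from the scattering invariant
  Q = integral q^2 (I(q) - B) dq, with a constant background B fitted on the
  high-q window, Guinier extrapolation to q = 0 and a q^-4 tail beyond the
  data;
* the concentration-dependent mass M = N_A (I(0)/c) / (delta_rho nu)^2,
  requiring absolute-scale I(0);
* a concentration-independent mass from the volume of correlation
  Vc = I(0) / integral q I(q) dq and QR = Vc^2 / Rg (power-law constants for
  the protein and nucleic acid classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import AVOGADRO, ScatteringParams
from .guinier import GuinierResult
from .sasio import SASProfile


class SizeMassError(ValueError):
    pass


@dataclass
class SizeReport:
    Vp: float | None = None                 # A^3
    Vp_over_M: float | None = None          # A^3 / Da
    M_from_I0c: float | None = None         # Da
    M_expected: float | None = None         # Da (from composition)
    ratio_to_expected: float | None = None  # M_from_I0c / M_expected
    M_conc_independent: float | None = None # Da
    conc_independent_method: str = ""
    flags: list = field(default_factory=list)


def _guinier_I(q, guinier: GuinierResult):
    return guinier.I0 * np.exp(-(q**2) * guinier.Rg**2 / 3.0)


def porod_volume(profile: SASProfile, guinier: GuinierResult,
                 q_cut="auto") -> float:
    """Porod volume in A^3 (scale-free).

    The invariant integral is assembled from three pieces: the Guinier
    model from 0 to the first data point, the trapezoidal integral of
    q^2 (I - B) over the data up to q_cut, and the analytic K/q tail beyond,
    where I ~ B + K q^-4 is fitted on the high-q window
    [max(0.2, 4/Rg), q_cut].
    """
    q, I = profile.q, profile.I
    if q_cut == "auto":
        q_cut = float(q[-1])
    mask = q <= q_cut
    q, I = q[mask], I[mask]
    q_hi = max(0.2, 4.0 / guinier.Rg)
    window = q >= q_hi
    if np.sum(window) < 5:
        window = q >= q[int(0.75 * len(q))]
    # Porod-plot linearization q^4 I = K + B q^4: well conditioned even on
    # oscillatory form factors, unlike a direct I = B + K q^-4 regression
    x = q[window] ** 4
    y = x * I[window]
    A = np.vstack([np.ones_like(x), x]).T
    (K, B), *_ = np.linalg.lstsq(A, y, rcond=None)
    # piece 1: Guinier extrapolation on [0, q_min]
    q0 = np.linspace(0.0, q[0], 50)
    piece0 = np.trapezoid(q0**2 * _guinier_I(q0, guinier), q0)
    # piece 2: data
    piece1 = np.trapezoid(q**2 * (I - B), q)
    # piece 3: Porod tail integral_qcut^inf K q^-2 dq = K / q_cut
    piece2 = max(K, 0.0) / q[-1]
    Q = piece0 + piece1 + piece2
    if Q <= 0:
        raise SizeMassError(f"negative scattering invariant (Q = {Q:.4g})")
    return float(2.0 * np.pi**2 * guinier.I0 / Q)


def mass_from_I0c(I0: float, c_mg_ml: float, params: ScatteringParams) -> float:
    """Mass in Da from absolute-scale forward scattering.

    M = N_A * (I(0)/c) / (delta_rho * nu)^2 with I(0) in cm^-1 and c
    converted from mg/ml to g/cm^3.  Exactly inverse to
    I(0) = c * M * (delta_rho * nu)^2 / N_A.
    """
    if c_mg_ml <= 0:
        raise SizeMassError("concentration must be positive")
    c = c_mg_ml * 1.0e-3                  # g/cm^3
    drho_m = params.delta_rho_M           # cm/g
    if drho_m == 0:
        raise SizeMassError("zero contrast: mass from I(0)/c undefined")
    return float(AVOGADRO * (I0 / c) / drho_m**2)


# volume-of-correlation power laws (q in A^-1, Rg in A, masses in Da)
_QR_CONSTANTS = {
    "protein": (0.1231, 1.0),
    "dna": (0.00934, 0.808),
    "rna": (0.00934, 0.808),
}


def mass_conc_independent(profile: SASProfile, guinier: GuinierResult,
                          kind: str = "protein") -> tuple[float, list]:
    """Concentration-independent mass from the volume of correlation.

    Vc = I(0) / integral_0^qmax q I(q) dq (Guinier-extended below the first
    data point), QR = Vc^2 / Rg, M = (QR / k)^(1/e) with the documented
    class constants.  Returns (mass, warnings); data truncated below
    q = 0.25 A^-1 yields a truncation warning.
    """
    if kind not in _QR_CONSTANTS:
        raise SizeMassError(f"unknown molecule class {kind!r}")
    warnings = []
    q, I = profile.q, profile.I
    if q[-1] < 0.25:
        warnings.append(
            f"q-range truncated at {q[-1]:.3g} A^-1 (< 0.25); the volume of "
            "correlation may be underestimated"
        )
    q0 = np.linspace(0.0, q[0], 50)
    head = np.trapezoid(q0 * _guinier_I(q0, guinier), q0)
    body = np.trapezoid(q * I, q)
    Vc = guinier.I0 / (head + body)
    QR = Vc**2 / guinier.Rg
    k, e = _QR_CONSTANTS[kind]
    M = (QR / k) ** (1.0 / e)
    return float(M), warnings


def size_panel(profile: SASProfile, guinier: GuinierResult,
               M_expected: float | None = None,
               concentration: float | None = None,
               params: ScatteringParams | None = None,
               kind: str = "protein") -> SizeReport:
    """Populate the scattering-particle-size panel with consistency flags."""
    report = SizeReport(M_expected=M_expected)
    try:
        report.Vp = porod_volume(profile, guinier)
    except SizeMassError as exc:
        report.flags.append(f"Porod volume unavailable: {exc}")
    if report.Vp is not None and M_expected:
        report.Vp_over_M = report.Vp / M_expected
    if concentration is not None and params is not None:
        if profile.intensity_scale != "absolute_cm":
            report.flags.append(
                "M from I(0)/c skipped: absolute intensity scale required"
            )
        else:
            report.M_from_I0c = mass_from_I0c(guinier.I0, concentration, params)
            if M_expected:
                report.ratio_to_expected = report.M_from_I0c / M_expected
    M_ci, warns = mass_conc_independent(profile, guinier, kind)
    report.M_conc_independent = M_ci
    report.conc_independent_method = "volume of correlation (Vc / QR power law)"
    report.flags.extend(warns)
    if report.ratio_to_expected is not None and not (
            0.75 <= report.ratio_to_expected <= 1.25):
        report.flags.append(
            f"M from I(0)/c is {report.ratio_to_expected:.2f} x the "
            "composition mass (outside the 25% consistency band)"
        )
    return report
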