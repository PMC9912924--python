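"""Synthetic scattering data with known ground truth.

Analytic form factors (homogeneous sphere, displaced two-sphere particle),
a Gaussian noise model with sigma(q) = relative_level * I(q) + floor, slit
smearing, and full neutron contrast-variation series over a list of solvent
D2O fractions.  Every generated series carries its exact ground truth so
recovery tests never need external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition import Assembly, SolventSpec, contrast as _composition_contrast, solvent_sld
from .pddf import BeamGeometry, smear
from .sasio import ModelCurve, SASProfile


@dataclass
class BodySpec:
    """Geometry and scattering-length densities of a 1- or 2-sphere particle.

    ``sld`` entries are absolute scattering-length densities (cm^-2); the
    contrast of body i in a given solvent is sld_i - rho_solvent.
    """

    shape: str                       # "sphere" | "two_sphere"
    radii: tuple                     # (R,) or (R1, R2), A
    separation: float = 0.0          # center-of-mass distance D, A
    sld: tuple = (1.0e10,)           # per body, cm^-2

    def __post_init__(self):
        if self.shape not in ("sphere", "two_sphere"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(R <= 0 for R in self.radii):
            raise ValueError("radii must be positive")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")

    def volumes(self):
        return tuple(4.0 / 3.0 * np.pi * R**3 for R in self.radii)


@dataclass
class NoiseSpec:
    """Relative Gaussian noise with an absolute floor; seed is mandatory."""

    relative_level: float = 0.0
    sigma_floor: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.relative_level < 0 or self.sigma_floor < 0:
            raise ValueError("noise levels must be >= 0")
        if (self.relative_level > 0 or self.sigma_floor > 0) and self.seed is None:
            raise ValueError("a seed is required for stochastic noise")


def _sphere_amplitude(q: np.ndarray, R: float) -> np.ndarray:
    """Normalized sphere form-factor amplitude F(0) = 1."""
    x = q * R
    out = np.ones_like(x)
    nz = x != 0
    xs = x[nz]
    out[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return out


def sphere_profile(R: float, delta_rho: float = 1.0e10,
                   number_density: float = 1.0,
                   q_grid=None, noise: NoiseSpec | None = None) -> SASProfile:
    """I(q) = n (delta_rho V)^2 [3 (sin qR - qR cos qR)/(qR)^3]^2.

    delta_rho in cm^-2, R in A; V is converted to cm^3 so that with
    number_density in cm^-3 the intensity is in cm^-1.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    q = np.asarray(q_grid if q_grid is not None
                   else np.linspace(1e-3, 0.5, 500), dtype=float)
    V_cm3 = 4.0 / 3.0 * np.pi * R**3 * 1.0e-24
    I = number_density * (delta_rho * V_cm3) ** 2 * _sphere_amplitude(q, R) ** 2
    return _apply_noise(q, I, noise, label=f"sphere_R{R:g}")


def two_body_profile(spec: BodySpec, q_grid=None,
                     noise: NoiseSpec | None = None) -> SASProfile:
    """Two-sphere Debye model.

    I(q) = A1^2 + A2^2 + 2 A1 A2 sin(qD)/(qD),  A_i = drho_i V_i F_i(q).
    For ``shape='sphere'`` the second body is absent.
    """
    q = np.asarray(q_grid if q_grid is not None
                   else np.linspace(1e-3, 0.5, 500), dtype=float)
    amps = []
    for R, rho in zip(spec.radii, spec.sld):
        V_cm3 = 4.0 / 3.0 * np.pi * R**3 * 1.0e-24
        amps.append(rho * V_cm3 * _sphere_amplitude(q, R))
    if spec.shape == "sphere" or len(amps) == 1:
        I = amps[0] ** 2
    else:
        x = q * spec.separation
        sinc = np.ones_like(x)
        nz = x != 0
        sinc[nz] = np.sin(x[nz]) / x[nz]
        I = amps[0] ** 2 + amps[1] ** 2 + 2.0 * amps[0] * amps[1] * sinc
    return _apply_noise(q, I, noise, label=f"{spec.shape}")


def two_body_components(spec: BodySpec, q_grid) -> dict:
    """Contrast-independent composite functions of the two-body model.

    Returns I11, I22 (volume-weighted component profiles, contrast divided
    out) and the cross term I12, such that
    I(q) = drho1^2 I11 + drho1 drho2 I12 + drho2^2 I22.
    """
    q = np.asarray(q_grid, dtype=float)
    V = [4.0 / 3.0 * np.pi * R**3 * 1.0e-24 for R in spec.radii]
    F1 = V[0] * _sphere_amplitude(q, spec.radii[0])
    F2 = V[1] * _sphere_amplitude(q, spec.radii[1])
    x = q * spec.separation
    sinc = np.ones_like(x)
    nz = x != 0
    sinc[nz] = np.sin(x[nz]) / x[nz]
    return {"I11": F1**2, "I22": F2**2, "I12": 2.0 * F1 * F2 * sinc,
            "I_homogeneous": F1**2 + F2**2 + 2.0 * F1 * F2 * sinc}


def _apply_noise(q, I, noise: NoiseSpec | None, label="") -> SASProfile:
    if noise is None or (noise.relative_level == 0 and noise.sigma_floor == 0):
        return SASProfile(q=q, I=I, sigma=None, label=label,
                          intensity_scale="absolute_cm")
    rng = np.random.default_rng(noise.seed)
    sigma = noise.relative_level * np.abs(I) + noise.sigma_floor
    sigma = np.maximum(sigma, 1e-12 * np.max(np.abs(I)))
    I_noisy = I + rng.normal(0.0, 1.0, size=len(q)) * sigma
    return SASProfile(q=q, I=I_noisy, sigma=sigma, label=label,
                      intensity_scale="absolute_cm")


@dataclass
class CVGroundTruth:
    """Exact quantities attached to a simulated contrast series."""

    match_point_pct: float
    component_rg: tuple              # (Rg1, Rg2), A
    separation: float
    contrasts: list                  # per condition (drho1, drho2), cm^-2
    components: dict                 # I11/I12/I22/I_homogeneous on the grid
    rg_by_condition: list            # whole-particle Rg per condition


@dataclass
class SimulatedSeries:
    f_d2o: list
    profiles: list
    concentration: float
    truth: CVGroundTruth


def _body_contrasts(spec: BodySpec, f: float) -> tuple:
    """Per-body contrasts at D2O fraction f.

    Body SLDs may be constants (cm^-2) or callables rho(f) — the latter is
    how assembly-derived bodies carry their H/D-exchange dependence.
    """
    rho_s = solvent_sld(SolventSpec(f), "neutron")
    return tuple((rho(f) if callable(rho) else rho) - rho_s
                 for rho in spec.sld)


def simulate_cv_series(spec, f_d2o_list, concentration: float = 5.0,
                       noise: NoiseSpec | None = None,
                       beam: BeamGeometry | None = None,
                       q_grid=None) -> SimulatedSeries:
    """Simulate a SANS contrast-variation series of a two-body particle.

    ``spec`` is a BodySpec (per-body SLDs, constant or callables of the D2O
    fraction) — or a 2-component Assembly, in which case each component is
    mapped onto a sphere of equal volume whose solvent-dependent SLD comes
    from the composition engine.  Ground truth (match point, component Rg,
    separation, composite functions, per-condition whole-particle Rg) is
    attached.
    """
    q = np.asarray(q_grid if q_grid is not None
                   else np.linspace(2e-3, 0.35, 400), dtype=float)
    if isinstance(spec, Assembly):
        spec = _bodyspec_from_assembly(spec)
    if len(spec.radii) != 2:
        raise ValueError("contrast-variation simulation needs a two-body spec")
    V = spec.volumes()
    profiles, contrasts, rgs = [], [], []
    rg_comp = tuple(np.sqrt(3.0 / 5.0) * R for R in spec.radii)
    seeds = None
    if noise is not None and noise.seed is not None:
        seeds = np.random.default_rng(noise.seed).integers(0, 2**31 - 1,
                                                           len(f_d2o_list))
    for i, f in enumerate(f_d2o_list):
        d1, d2 = _body_contrasts(spec, f)
        cond = BodySpec(shape="two_sphere", radii=spec.radii,
                        separation=spec.separation,
                        sld=(d1, d2))
        pt_noise = None
        if seeds is not None:
            pt_noise = NoiseSpec(noise.relative_level, noise.sigma_floor,
                                 int(seeds[i]))
        # absolute contrasts enter through the two-body amplitudes directly
        prof = _two_body_with_contrasts(cond, q, pt_noise, f)
        if beam is not None and beam.kind == "slit":
            smeared = smear(ModelCurve(q=q, I_model=prof.I), beam)
            prof = SASProfile(q=q, I=smeared.I_model, sigma=prof.sigma,
                              label=prof.label, intensity_scale="absolute_cm")
        profiles.append(prof)
        contrasts.append((d1, d2))
        w1, w2 = d1 * V[0], d2 * V[1]
        tot = w1 + w2
        if tot != 0:
            f1 = w1 / tot
            rg2 = (f1 * rg_comp[0] ** 2 + (1 - f1) * rg_comp[1] ** 2
                   + f1 * (1 - f1) * spec.separation ** 2)
            rgs.append(float(np.sign(rg2) * np.sqrt(abs(rg2))))
        else:
            rgs.append(float("nan"))
    # match point: zero of total contrast drho1 V1 + drho2 V2 (affine in f
    # because both the solvent SLD and any exchange model are linear)
    w0 = sum(d * v for d, v in zip(_body_contrasts(spec, 0.0), V))
    w1_ = sum(d * v for d, v in zip(_body_contrasts(spec, 1.0), V))
    mp = 100.0 * w0 / (w0 - w1_) if w0 != w1_ else float("nan")
    truth = CVGroundTruth(
        match_point_pct=float(mp),
        component_rg=rg_comp,
        separation=spec.separation,
        contrasts=contrasts,
        components=two_body_components(spec, q),
        rg_by_condition=rgs,
    )
    return SimulatedSeries(f_d2o=list(f_d2o_list), profiles=profiles,
                           concentration=concentration, truth=truth)


def _two_body_with_contrasts(cond: BodySpec, q, noise, f) -> SASProfile:
    prof = two_body_profile(cond, q_grid=q, noise=noise)
    prof.label = f"cv_{int(round(100 * f))}pctD2O"
    return prof


def _bodyspec_from_assembly(assembly: Assembly) -> BodySpec:
    if len(assembly.components) != 2:
        raise ValueError("assembly must have exactly two components")
    radii, slds = [], []
    for comp in assembly.components:
        sub = Assembly([comp])
        radii.append((3.0 * sub.volume() / (4.0 * np.pi)) ** (1.0 / 3.0))

        def rho_of_f(f, _sub=sub):
            return _composition_contrast(_sub, SolventSpec(f), "neutron").rho

        slds.append(rho_of_f)
    return BodySpec(shape="two_sphere", radii=tuple(radii),
                    separation=float(sum(radii)), sld=tuple(slds))
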