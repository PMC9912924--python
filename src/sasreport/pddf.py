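"""Pair-distance distribution analysis: regularized indirect Fourier
transform (IFT), slit smearing and desmearing.

The forward model is the Debye kernel

    I(q) = 4 pi * integral_0^dmax P(r) sin(qr)/(qr) dr

with P(0) = P(dmax) = 0 enforced by construction.  The inverse problem is
solved on a fixed r-grid by penalized least squares: chi^2 plus alpha times
a second-derivative roughness penalty, optionally under non-negativity.
``alpha='auto'`` picks the corner of the L-curve.

Slit-geometry data are handled by smearing the forward kernel with a
trapezoidal beam-length profile W(t):

    I_s(q) = integral W(t) I(sqrt(q^2 + t^2)) dt / integral W(t) dt
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .gof import cormap_pvalue
from .sasio import ModelCurve, SASProfile


class PDDFError(ValueError):
    pass


@dataclass
class BeamGeometry:
    """Point geometry, or a slit with a trapezoidal length profile.

    The trapezoid is parameterized by its plateau half-width and base
    half-width in A^-1 (0 <= plateau <= base).
    """

    kind: str = "point"              # "point" | "slit"
    plateau: float = 0.0
    base: float = 0.0

    def __post_init__(self):
        if self.kind not in ("point", "slit"):
            raise PDDFError(f"unknown beam geometry {self.kind!r}")
        if self.kind == "slit" and not (0.0 <= self.plateau <= self.base):
            raise PDDFError("need 0 <= plateau <= base for a slit profile")
        if self.kind == "slit" and self.base == 0.0:
            self.kind = "point"      # delta-function profile: identity

    def weights(self, n: int = 101):
        """(t, W(t)) nodes on [0, base], normalized to integrate to 1."""
        t = np.linspace(0.0, self.base, n)
        w = np.ones_like(t)
        ramp = t > self.plateau
        if self.base > self.plateau:
            w[ramp] = (self.base - t[ramp]) / (self.base - self.plateau)
        norm = np.trapezoid(w, t)
        return t, w / norm


@dataclass
class PDDFResult:
    r: np.ndarray
    p: np.ndarray
    d_max: float
    alpha: float
    I0: float
    sigma_I0: float
    Rg: float
    sigma_Rg: float
    fit_q_range: tuple
    chi2: float
    cormap_p: float
    n_active: int = 0
    warnings: list = field(default_factory=list)
    scan_scores: dict | None = None

    def regularized_intensity(self, q, beam: BeamGeometry | None = None) -> np.ndarray:
        """Forward-model intensity of the fitted P(r) on an arbitrary q-grid."""
        beam = beam or BeamGeometry()
        A = _kernel(np.asarray(q, dtype=float), self.r, beam)
        return A @ self.p


def _sinc_qr(q, r):
    """sin(qr)/(qr) with the q*r -> 0 limit handled."""
    x = np.outer(q, r)
    out = np.ones_like(x)
    nz = x != 0
    out[nz] = np.sin(x[nz]) / x[nz]
    return out


def _kernel(q, r, beam: BeamGeometry) -> np.ndarray:
    """Quadrature matrix A with I(q) = A @ p for p sampled on r."""
    dr = r[1] - r[0]
    w = np.full(len(r), dr)
    w[0] = w[-1] = dr / 2.0
    if beam.kind == "point":
        return 4.0 * np.pi * _sinc_qr(q, r) * w
    t, wt = beam.weights()
    dt = t[1] - t[0]
    acc = np.zeros((len(q), len(r)))
    trap = np.full(len(t), dt)
    trap[0] = trap[-1] = dt / 2.0
    for ti, wti, tri in zip(t, wt, trap):
        q_eff = np.sqrt(q**2 + ti**2)
        acc += wti * tri * _sinc_qr(q_eff, r)
    return 4.0 * np.pi * acc * w


def smear(curve: ModelCurve, beam: BeamGeometry) -> ModelCurve:
    """Slit-smear a tabulated model curve.

    The curve is interpolated on [q_min, q_max] and extended beyond q_max by
    a Porod q^-4 tail fitted to the last decade of points.  Point geometry
    returns the input unchanged.
    """
    if beam.kind == "point":
        return ModelCurve(q=curve.q.copy(), I_model=curve.I_model.copy(),
                          label=curve.label)
    q, I = curve.q, curve.I_model
    n_tail = max(5, len(q) // 10)
    # Porod-plot fit q^4 I = K + B q^4 on the tail: the extension
    # I = B + K/q^4 reduces to the exact constant for flat curves
    x = q[-n_tail:] ** 4
    A = np.vstack([np.ones_like(x), x]).T
    (K, B), *_ = np.linalg.lstsq(A, x * I[-n_tail:], rcond=None)

    def evaluate(u):
        u = np.asarray(u)
        inside = u <= q[-1]
        out = np.empty_like(u, dtype=float)
        out[inside] = np.interp(u[inside], q, I)
        out[~inside] = B + K / u[~inside] ** 4
        return out

    t, wt = beam.weights()
    dt = t[1] - t[0]
    trap = np.full(len(t), dt)
    trap[0] = trap[-1] = dt / 2.0
    I_s = np.zeros_like(I)
    for ti, wti, tri in zip(t, wt, trap):
        I_s += wti * tri * evaluate(np.sqrt(q**2 + ti**2))
    return ModelCurve(q=q.copy(), I_model=I_s, label=curve.label)


def desmear(profile: SASProfile, pr_model: PDDFResult,
            beam: BeamGeometry) -> SASProfile:
    """Desmear by point-by-point multiplication with the ratio of the
    unsmeared to the smeared intensity of the fitted P(r) model.

    sigma is scaled by the same ratio.  Point geometry is the identity.
    """
    if beam.kind == "point":
        return profile
    I_ideal = pr_model.regularized_intensity(profile.q)
    I_smeared = pr_model.regularized_intensity(profile.q, beam)
    bad = I_smeared == 0
    if np.any(bad):
        qb = profile.q[bad][0]
        raise PDDFError(f"desmearing ratio undefined: smeared model is zero at q = {qb:.5g}")
    ratio = I_ideal / I_smeared
    return SASProfile(
        q=profile.q.copy(), I=profile.I * ratio,
        sigma=None if profile.sigma is None else profile.sigma * np.abs(ratio),
        intensity_scale=profile.intensity_scale,
        label=profile.label, source_meta=dict(profile.source_meta),
    )


def _solve(Aw, yw, D, alpha, nonneg):
    """Minimize ||Aw p - yw||^2 + alpha ||D p||^2, optionally p >= 0."""
    stacked = np.vstack([Aw, np.sqrt(alpha) * D])
    rhs = np.concatenate([yw, np.zeros(D.shape[0])])
    if nonneg:
        p, _ = nnls(stacked, rhs)
    else:
        p, *_ = np.linalg.lstsq(stacked, rhs, rcond=None)
    return p


def _roughness(n_interior, dr):
    """Second-difference operator on the interior nodes (zero endpoints)."""
    D = np.zeros((n_interior, n_interior))
    for i in range(n_interior):
        D[i, i] = -2.0
        if i > 0:
            D[i, i - 1] = 1.0
        if i < n_interior - 1:
            D[i, i + 1] = 1.0
    return D / dr**2


def ift(profile: SASProfile, d_max: float, alpha="auto",
        beam: BeamGeometry | None = None, nonneg: bool = True,
        n_r: int = 201, q_range: tuple | None = None) -> PDDFResult:
    """Regularized indirect Fourier transform to P(r).

    Parameters
    ----------
    profile : SASProfile
        Data; if uncertainties are present the fit is error-weighted.
    d_max : float
        Maximum particle dimension in A (P is forced to zero there).
    alpha : float or "auto"
        Roughness weight; "auto" picks the L-curve corner.
    beam : BeamGeometry
        When slit, the forward kernel is smeared before fitting, so the
        returned P(r) describes the ideal (desmeared) particle.
    nonneg : bool
        Constrain P(r) >= 0 (disable for multi-phase contrast data).
    """
    if d_max <= 0:
        raise PDDFError("d_max must be positive")
    beam = beam or BeamGeometry()
    data = profile if q_range is None else profile.window(*q_range)
    q, I = data.q, data.I
    sigma = data.sigma if data.sigma is not None else np.full_like(I, max(np.max(np.abs(I)), 1e-30) * 1e-3)
    r = np.linspace(0.0, d_max, n_r)
    dr = r[1] - r[0]
    A_full = _kernel(q, r, beam)
    A = A_full[:, 1:-1]                      # endpoint values pinned to zero
    Aw = A / sigma[:, None]
    yw = I / sigma
    D = _roughness(n_r - 2, dr)
    # natural scale making alpha dimensionless
    scale = np.linalg.norm(Aw, "fro") ** 2 / np.linalg.norm(D, "fro") ** 2
    if alpha == "auto":
        alphas = scale * np.logspace(-10, 0, 21)
        log_rho, log_eta = [], []
        sols = []
        for a in alphas:
            p = _solve(Aw, yw, D, a, nonneg)
            rho = np.linalg.norm(Aw @ p - yw)
            eta = np.linalg.norm(D @ p)
            log_rho.append(np.log(max(rho, 1e-300)))
            log_eta.append(np.log(max(eta, 1e-300)))
            sols.append(p)
        lr, le = np.array(log_rho), np.array(log_eta)
        # discrete curvature of the L-curve; corner = max curvature
        curv = np.full(len(alphas), -np.inf)
        for i in range(1, len(alphas) - 1):
            x1, y1 = lr[i - 1], le[i - 1]
            x2, y2 = lr[i], le[i]
            x3, y3 = lr[i + 1], le[i + 1]
            a2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
            b2 = (x3 - x2) ** 2 + (y3 - y2) ** 2
            c2 = (x3 - x1) ** 2 + (y3 - y1) ** 2
            area2 = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
            denom = np.sqrt(a2 * b2 * c2)
            if denom > 0:
                curv[i] = 2 * area2 / denom
        best = int(np.argmax(curv))
        if not np.isfinite(curv[best]):
            raise PDDFError(
                "alpha=auto failed to bracket an L-curve corner; residual norms: "
                + ", ".join(f"{v:.3g}" for v in np.exp(lr))
            )
        alpha_used = float(alphas[best])
        p_int = sols[best]
    else:
        alpha_used = float(alpha) * scale
        p_int = _solve(Aw, yw, D, alpha_used, nonneg)
    p = np.zeros(n_r)
    p[1:-1] = p_int
    # ---- moments and fit statistics ----
    integral = np.trapezoid(p, r)
    if integral <= 0:
        raise PDDFError("fitted P(r) has non-positive integral")
    I0 = 4.0 * np.pi * integral
    Rg2 = np.trapezoid(r**2 * p, r) / (2.0 * integral)
    Rg = float(np.sqrt(max(Rg2, 0.0)))
    resid = (A @ p_int - I) / sigma
    active = p_int > 0 if nonneg else np.ones(len(p_int), dtype=bool)
    n_active = int(np.sum(active))
    # effective number of parameters = trace of the hat matrix of the
    # penalized problem on the active set (much smaller than the grid size
    # when the roughness penalty is doing its job)
    Aact = Aw[:, active]
    AtA = Aact.T @ Aact
    Ract = (D.T @ D)[np.ix_(active, active)]
    try:
        t_eff = float(np.trace(np.linalg.solve(AtA + alpha_used * Ract, AtA)))
    except np.linalg.LinAlgError:
        t_eff = float(n_active)
    dof = max(len(q) - t_eff, 1.0)
    chi2 = float(np.sum(resid**2)) / dof
    longest, cormap_p = cormap_pvalue(-resid >= 0)
    # uncertainty of the moments from the weighted linear problem on the
    # active set (regularized covariance; indicative rather than exact)
    try:
        cov = np.linalg.inv(AtA + alpha_used * Ract) * max(chi2, 1.0)
        g0 = np.full(n_active, 4.0 * np.pi * dr)
        var_I0 = float(g0 @ cov @ g0)
        sigma_I0 = np.sqrt(max(var_I0, 0.0))
        r_act = r[1:-1][active]
        gr = dr * (r_act**2 - 2.0 * Rg2) / (2.0 * integral)
        var_Rg2 = float(gr @ cov @ gr)
        sigma_Rg = np.sqrt(max(var_Rg2, 0.0)) / (2.0 * Rg) if Rg > 0 else 0.0
    except np.linalg.LinAlgError:
        sigma_I0 = sigma_Rg = float("nan")
    return PDDFResult(
        r=r, p=p, d_max=float(d_max), alpha=alpha_used,
        I0=float(I0), sigma_I0=float(sigma_I0), Rg=Rg, sigma_Rg=float(sigma_Rg),
        fit_q_range=(float(q[0]), float(q[-1])),
        chi2=chi2, cormap_p=cormap_p, n_active=n_active,
    )


def scan_dmax(profile: SASProfile, d_max_grid, **ift_kwargs) -> PDDFResult:
    """Pick d_max from a candidate grid.

    Each candidate is scored by the fit chi^2 plus penalties for
    oscillatory P(r) (extra local extrema) and for P(r) not approaching
    zero smoothly at d_max.  A flat score across the grid (pure-noise data)
    attaches an "unstable d_max" warning to the returned result.
    """
    d_max_grid = np.atleast_1d(np.asarray(d_max_grid, dtype=float))
    results, scores = [], []
    for dm in d_max_grid:
        try:
            res = ift(profile, dm, **ift_kwargs)
        except PDDFError:
            results.append(None)
            scores.append(np.inf)
            continue
        pmax = np.max(np.abs(res.p)) or 1.0
        dp = np.diff(res.p)
        n_extrema = int(np.sum(np.diff(np.sign(dp[np.abs(dp) > 1e-12 * pmax])) != 0))
        osc_penalty = 0.25 * max(0, n_extrema - 1)
        neg_penalty = 2.0 * float(np.sum(np.clip(-res.p, 0, None)) / (pmax * len(res.p)))
        tail = np.mean(np.abs(res.p[-max(3, len(res.p) // 20):])) / pmax
        results.append(res)
        scores.append(res.chi2 + osc_penalty + neg_penalty + 2.0 * tail)
    scores = np.asarray(scores)
    if not np.any(np.isfinite(scores)):
        raise PDDFError("no d_max candidate produced a valid fit")
    # parsimony: the smallest d_max whose score is indistinguishable from
    # the best (overestimating d_max rarely worsens the fit)
    s_min = float(np.nanmin(scores[np.isfinite(scores)]))
    threshold = s_min + max(0.05 * abs(s_min), 0.02)
    best = int(np.argmin(np.where(scores <= threshold, d_max_grid, np.inf)))
    res = results[best]
    chi2s = np.array([r.chi2 if r is not None else np.nan for r in results])
    chi2s = chi2s[np.isfinite(chi2s)]
    if len(chi2s) > 2 and (chi2s.max() - chi2s.min()) < 0.1 * max(chi2s.min(), 1e-12):
        res.warnings.append(
            "unstable d_max: fit quality is flat across the candidate grid")
    res.scan_scores = {float(d): float(s) for d, s in zip(d_max_grid, scores)}
    return res


def sphere_pddf(r, R: float) -> np.ndarray:
    """Closed-form P(r) of a homogeneous sphere of radius R (unit I(0)/4pi).

    P(r) is proportional to r^2 (1 - 3u/2 + u^3/2) with u = r/d, d = 2R,
    normalized so that the integral over [0, d] is 1.
    """
    d = 2.0 * R
    u = np.asarray(r, dtype=float) / d
    p = 24.0 * u**2 * (1.0 - 1.5 * u + 0.5 * u**3) / d
    p[np.asarray(r) > d] = 0.0
    return p
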