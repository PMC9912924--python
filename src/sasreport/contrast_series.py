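"""Contrast-variation analysis of two-component particles.

Given measurements of the same particle in solvents of different D2O
fraction, this module extracts:

* the experimental solvent match point from the linear dependence of
  sign * sqrt(I(0)/c) on the D2O fraction;
* the Stuhrmann decomposition Rg_obs^2 = Rm^2 + alpha/drho - beta/drho^2 of
  the contrast dependence of the radius of gyration;
* the parallel-axis decomposition
  Rg_obs^2 = f1 R1^2 + f2 R2^2 + f1 f2 D^2 with contrast-weighted fractions
  f_i = drho_i V_i / sum_j drho_j V_j;
* the composite scattering functions I11, I12, I22 defined by
  I_k(q) = drho1_k^2 I11 + drho1_k drho2_k I12 + drho2_k^2 I22, whose sum
  is the profile the particle would show at uniform internal contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .guinier import GuinierResult
from .pddf import PDDFResult
from .sasio import SASProfile


class ContrastError(ValueError):
    pass


@dataclass
class ContrastPoint:
    """One solvent condition of a contrast series."""

    f_d2o: float
    profile: SASProfile | None = None
    c: float | None = None                  # mg/ml
    guinier: GuinierResult | None = None
    pddf: PDDFResult | None = None
    delta_rho: float | None = None          # whole particle, cm^-2
    delta_rho_components: tuple | None = None  # (drho1, drho2), cm^-2

    def __post_init__(self):
        if not 0.0 <= self.f_d2o <= 1.0:
            raise ContrastError("f_d2o must be in [0, 1]")


@dataclass
class ContrastSeries:
    points: list

    def __post_init__(self):
        fs = [p.f_d2o for p in self.points]
        if len(set(fs)) != len(fs):
            raise ContrastError("f_d2o values must be distinct")
        self.points = sorted(self.points, key=lambda p: p.f_d2o)


@dataclass
class MatchPointResult:
    match_point_pct: float
    sigma_pct: float
    slope: float
    intercept: float
    extrapolated: bool = False


@dataclass
class ComponentDecomposition:
    Rm: float | None = None
    sigma_Rm: float | None = None
    alpha: float | None = None
    sigma_alpha: float | None = None
    beta: float | None = None
    sigma_beta: float | None = None
    R1: float | None = None
    sigma_R1: float | None = None
    R2: float | None = None
    sigma_R2: float | None = None
    D: float | None = None
    sigma_D: float | None = None
    flags: list = field(default_factory=list)


def _weighted_lstsq(X, y, w):
    """Weighted least squares with column equilibration.

    Column norms can differ by tens of orders of magnitude here (powers of
    1/contrast in cm^2), so each column is scaled to unit norm before the
    solve and the coefficients are scaled back.  Returns beta, cov(beta).
    """
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    col = np.linalg.norm(Xw, axis=0)
    col[col == 0] = 1.0
    Xs = Xw / col
    beta_s, *_ = np.linalg.lstsq(Xs, yw, rcond=None)
    cov_s = np.linalg.inv(Xs.T @ Xs)
    dof = max(len(y) - X.shape[1], 1)
    s2 = max(float(np.sum((yw - Xs @ beta_s) ** 2)) / dof, 1.0)
    beta = beta_s / col
    cov = (cov_s * s2) / np.outer(col, col)
    return beta, cov


def match_point_experimental(series: ContrastSeries) -> MatchPointResult:
    """Experimental match point from the root of a weighted linear fit of
    sign * sqrt(I(0)/c) against the D2O volume fraction.

    Signs are assigned automatically: positive at and below the condition
    with the smallest |I(0)|, negative above it (the coherent amplitude
    changes sign when the mean contrast crosses zero).  If all points end
    up on one side, the fitted root is flagged as extrapolated.
    """
    pts = [p for p in series.points if p.guinier is not None and p.c]
    if len(pts) < 2:
        raise ContrastError("need at least two points with I(0) and c")
    f = np.array([p.f_d2o for p in pts])
    I0 = np.array([p.guinier.I0 for p in pts])
    sI0 = np.array([p.guinier.sigma_I0 for p in pts])
    c = np.array([p.c for p in pts])
    i_min = int(np.argmin(np.abs(I0)))
    mag = np.sqrt(np.abs(I0) / c)
    sigma_y = np.where(I0 != 0, mag * sI0 / (2.0 * np.abs(I0)), np.inf)
    w = 1.0 / sigma_y**2
    if not np.all(np.isfinite(w)):
        w = np.ones_like(mag)
    X = np.vstack([np.ones_like(f), f]).T
    # the condition nearest the crossing could lie on either side; try both
    # signs for it and keep the better weighted fit
    best = None
    for sign_min in (1.0, -1.0):
        sign = np.where(f < f[i_min], 1.0, np.where(f > f[i_min], -1.0, sign_min))
        y = sign * mag
        (a, b), cov = _weighted_lstsq(X, y, w)
        ss = float(np.sum(w * (y - (a + b * f)) ** 2))
        bracketed = np.any(y > 0) and np.any(y < 0)
        # smaller misfit wins; on (near-)ties prefer the assignment that
        # brackets the crossing (a one-sided fit cannot locate the root)
        ss_norm = ss / max(float(np.sum(w * y**2)), 1e-300)
        key = (round(ss_norm, 12), 0 if bracketed else 1)
        if best is None or key < best[0]:
            best = (key, a, b, cov, y)
    _, a, b, cov, y = best
    if b == 0:
        raise ContrastError("no contrast dependence: zero slope")
    root = -a / b
    # delta method for var(-a/b)
    grad = np.array([-1.0 / b, a / b**2])
    var = float(grad @ cov @ grad)
    extrapolated = not (np.any(y > 0) and np.any(y < 0))
    return MatchPointResult(
        match_point_pct=float(100.0 * root),
        sigma_pct=float(100.0 * np.sqrt(max(var, 0.0))),
        slope=float(b), intercept=float(a), extrapolated=extrapolated,
    )


def stuhrmann_fit(inv_drho, rg2, sigma_rg2=None,
                  constrain_beta: bool = False) -> ComponentDecomposition:
    """Quadratic Stuhrmann fit Rg^2 = Rm^2 + alpha * x - beta * x^2 with
    x = 1/drho_mean (A^2 per unit 1/contrast).

    With exactly three points the fit is exact.  Near-collinear x values
    produce a conditioning flag.
    """
    x = np.asarray(inv_drho, dtype=float)
    y = np.asarray(rg2, dtype=float)
    n_par = 2 if constrain_beta else 3
    if len(x) < n_par:
        raise ContrastError(
            f"need >= {n_par} contrast points for the Stuhrmann fit"
        )
    if len(np.unique(np.round(x, 12))) < n_par:
        raise ContrastError("1/drho values are not distinct enough")
    w = (np.ones_like(y) if sigma_rg2 is None
         else 1.0 / np.asarray(sigma_rg2, dtype=float) ** 2)
    cols = [np.ones_like(x), x] if constrain_beta else [np.ones_like(x), x, -x**2]
    X = np.vstack(cols).T
    beta_hat, cov = _weighted_lstsq(X, y, w)
    out = ComponentDecomposition(
        Rm=float(np.sqrt(max(beta_hat[0], 0.0))),
        alpha=float(beta_hat[1]),
        sigma_alpha=float(np.sqrt(cov[1, 1])),
        beta=0.0 if constrain_beta else float(beta_hat[2]),
        sigma_beta=0.0 if constrain_beta else float(np.sqrt(cov[2, 2])),
    )
    if beta_hat[0] > 0:
        out.sigma_Rm = float(np.sqrt(cov[0, 0]) / (2.0 * out.Rm))
    cond = np.linalg.cond(X)
    if cond > 1e6:
        out.flags.append(f"near-collinear 1/drho values (condition number {cond:.2g})")
    return out


def parallel_axis(f1, rg2, sigma_rg2=None) -> ComponentDecomposition:
    """Parallel-axis decomposition: solve Rg^2 = f1 R1^2 + f2 R2^2
    + f1 f2 D^2 for (R1^2, R2^2, D^2) by weighted least squares.

    ``f1`` are the contrast-weighted fractions of component 1 at each
    condition (f2 = 1 - f1).  Negative solutions are flagged, not raised.
    """
    f1 = np.asarray(f1, dtype=float)
    y = np.asarray(rg2, dtype=float)
    if len(f1) < 3:
        raise ContrastError("need >= 3 contrast points for the parallel-axis fit")
    f2 = 1.0 - f1
    X = np.vstack([f1, f2, f1 * f2]).T
    if np.linalg.matrix_rank(X) < 3:
        lev = ", ".join(f"f1={v:.3f}" for v in f1)
        raise ContrastError(f"singular design matrix; contrast leverage: {lev}")
    w = (np.ones_like(y) if sigma_rg2 is None
         else 1.0 / np.asarray(sigma_rg2, dtype=float) ** 2)
    beta_hat, cov = _weighted_lstsq(X, y, w)
    out = ComponentDecomposition()
    names = ("R1", "R2", "D")
    for i, name in enumerate(names):
        val = beta_hat[i]
        if val < 0:
            out.flags.append(f"negative solution for {name}^2 ({val:.3g} A^2)")
            setattr(out, name, float(-np.sqrt(-val)))
        else:
            setattr(out, name, float(np.sqrt(val)))
            if val > 0:
                setattr(out, f"sigma_{name}",
                        float(np.sqrt(cov[i, i]) / (2.0 * np.sqrt(val))))
    return out


def contrast_fractions(drho_components, volumes) -> np.ndarray:
    """f_i = drho_i V_i / sum_j drho_j V_j at one condition."""
    w = np.asarray(drho_components, dtype=float) * np.asarray(volumes, dtype=float)
    total = np.sum(w)
    if total == 0:
        raise ContrastError("zero mean contrast: fractions undefined")
    return w / total


@dataclass
class CompositeFunctions:
    q: np.ndarray
    I11: np.ndarray
    I12: np.ndarray
    I22: np.ndarray
    I_homogeneous: np.ndarray
    condition_number: float
    interpolated: bool = False


def composite_functions(series: ContrastSeries,
                        q_grid=None) -> CompositeFunctions:
    """Decompose a contrast series into component scattering functions.

    At each q the linear system I_k = drho1_k^2 I11 + drho1_k drho2_k I12 +
    drho2_k^2 I22 is solved across the contrasts k by (sigma-weighted)
    least squares.  Requires >= 3 conditions with per-component contrasts
    of rank 3.  I_homogeneous = I11 + I12 + I22.
    """
    pts = [p for p in series.points
           if p.profile is not None and p.delta_rho_components is not None]
    if len(pts) < 3:
        raise ContrastError("need >= 3 conditions with component contrasts")
    interpolated = False
    if q_grid is None:
        q_grid = pts[0].profile.q
        for p in pts[1:]:
            if len(p.profile.q) != len(q_grid) or not np.allclose(p.profile.q, q_grid):
                interpolated = True
    q_grid = np.asarray(q_grid, dtype=float)
    design = np.array([
        [p.delta_rho_components[0] ** 2,
         p.delta_rho_components[0] * p.delta_rho_components[1],
         p.delta_rho_components[1] ** 2]
        for p in pts
    ])
    # rescale contrasts to order unity for conditioning
    scale = np.max(np.abs([p.delta_rho_components for p in pts]))
    design_s = design / scale**2
    if np.linalg.matrix_rank(design_s, tol=1e-10) < 3:
        raise ContrastError("contrast design has rank < 3 across conditions")
    cond = float(np.linalg.cond(design_s))
    I_mat = np.empty((len(pts), len(q_grid)))
    W = np.empty((len(pts), len(q_grid)))
    for k, p in enumerate(pts):
        if interpolated or len(p.profile.q) != len(q_grid) \
                or not np.allclose(p.profile.q, q_grid):
            I_mat[k] = np.interp(q_grid, p.profile.q, p.profile.I)
            W[k] = 1.0
            interpolated = True
        else:
            I_mat[k] = p.profile.I
            W[k] = (1.0 if p.profile.sigma is None
                    else 1.0 / np.interp(q_grid, p.profile.q, p.profile.sigma))
    sol = np.empty((3, len(q_grid)))
    for j in range(len(q_grid)):
        Aw = design_s * W[:, j, None]
        yw = I_mat[:, j] * W[:, j]
        sol[:, j], *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    sol /= scale**2
    I11, I12, I22 = sol
    return CompositeFunctions(
        q=q_grid, I11=I11, I12=I12, I22=I22,
        I_homogeneous=I11 + I12 + I22,
        condition_number=cond, interpolated=interpolated,
    )
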