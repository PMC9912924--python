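"""Goodness of fit between data and model curves.

Two complementary statistics are computed for every fit: the reduced chi^2
of the error-weighted residuals, and the correlation-map (CorMap) longest-run
P-value — the probability that n independent fair sign flips contain a run of
identical signs at least as long as the longest run observed in the residual
sign sequence.  The run-length distribution is computed exactly by the
standard composition recurrence, not by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .sasio import ModelCurve, SASProfile


@dataclass
class FitAssessment:
    chi2: float                    # reduced chi^2 (scale-fitted dof handling)
    chi2_unreduced_n: float        # sum of squares / N, for reference
    n_points: int
    scale: float | None            # fitted multiplicative factor, or None
    residuals: np.ndarray          # (I_data - s I_model) / sigma
    q: np.ndarray
    longest_run: int
    cormap_p: float
    run_interval: tuple            # (q_lo, q_hi) of the longest run
    interpolated: bool = False


@lru_cache(maxsize=None)
def _n_strings_max_run_le(n: int, m: int) -> int:
    """Number of binary strings of length n whose longest run is <= m.

    Equal to 2 * C(n) where C counts compositions of n into parts <= m.
    """
    if m <= 0:
        return 1 if n == 0 else 0
    comp = [0] * (n + 1)
    comp[0] = 1
    for k in range(1, n + 1):
        comp[k] = sum(comp[k - j] for j in range(1, min(m, k) + 1))
    return 2 * comp[n] if n > 0 else 1


def longest_run_pvalue(n: int, c: int) -> float:
    """P(longest run of identical signs >= c) in n fair independent flips."""
    if n < 1:
        raise ValueError("need at least one sign")
    if c <= 1:
        return 1.0
    if c > n:
        return 0.0
    p = 1 - Fraction(_n_strings_max_run_le(n, c - 1), 2**n)
    return float(p)


def cormap_pvalue(signs) -> tuple[int, float]:
    """Longest run C of identical signs and its exact P-value.

    ``signs`` is any sequence whose elements compare as +/- (booleans,
    +1/-1, '+'/'-').  Zeros are treated as positive (deterministic
    tie-break, documented).
    """
    arr = list(signs)
    if len(arr) == 0:
        raise ValueError("empty sign sequence")

    def _pos(s):
        if isinstance(s, str):
            return s != "-"
        if isinstance(s, (bool, np.bool_)):
            return bool(s)
        return s >= 0

    bits = [_pos(s) for s in arr]
    longest = run = 1
    for a, b in zip(bits, bits[1:]):
        run = run + 1 if a == b else 1
        longest = max(longest, run)
    return longest, longest_run_pvalue(len(bits), longest)


def _longest_run_interval(bits: np.ndarray) -> tuple[int, int]:
    """(start, end) indices (inclusive) of the first longest run."""
    best = (0, 0)
    start = 0
    for i in range(1, len(bits) + 1):
        if i == len(bits) or bits[i] != bits[start]:
            if i - 1 - start > best[1] - best[0]:
                best = (start, i - 1)
            start = i
    return best


def chi2(data: SASProfile, model: ModelCurve,
         fit_scale: bool = True) -> FitAssessment:
    """Reduced chi^2 and CorMap statistics for a model fit.

    When the model q-grid differs from the data it is linearly interpolated
    (flagged on the result).  With ``fit_scale`` the analytic optimal
    multiplicative factor s = sum(I_d I_m / s^2) / sum(I_m^2 / s^2) is
    applied and one degree of freedom is consumed.
    """
    if data.sigma is None:
        raise ValueError("chi^2 requires data uncertainties")
    interpolated = False
    if len(model.q) != len(data.q) or not np.allclose(model.q, data.q):
        if data.q[0] < model.q[0] - 1e-12 or data.q[-1] > model.q[-1] + 1e-12:
            raise ValueError(
                "model grid does not cover the data q-range "
                f"({model.q[0]:.4g}-{model.q[-1]:.4g} vs "
                f"{data.q[0]:.4g}-{data.q[-1]:.4g})"
            )
        I_m = np.interp(data.q, model.q, model.I_model)
        interpolated = True
    else:
        I_m = model.I_model
    w = 1.0 / data.sigma**2
    if fit_scale:
        s = float(np.sum(w * data.I * I_m) / np.sum(w * I_m**2))
        k = 1
    else:
        s = 1.0
        k = 0
    resid = (data.I - s * I_m) / data.sigma
    n = len(resid)
    ss = float(np.sum(resid**2))
    bits = resid >= 0
    longest, p = cormap_pvalue(bits)
    lo, hi = _longest_run_interval(bits)
    return FitAssessment(
        chi2=ss / max(n - k, 1),
        chi2_unreduced_n=ss / n,
        n_points=n,
        scale=s if fit_scale else None,
        residuals=resid,
        q=data.q.copy(),
        longest_run=longest,
        cormap_p=p,
        run_interval=(float(data.q[lo]), float(data.q[hi])),
        interpolated=interpolated,
    )


def residual_series(data: SASProfile, model: ModelCurve,
                    scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """(q, error-weighted residuals) ready for plotting or serialization.

    Sign convention: positive residual means the data lie above the scaled
    model.
    """
    if data.sigma is None:
        raise ValueError("residual series requires data uncertainties")
    I_m = np.interp(data.q, model.q, model.I_model)
    return data.q.copy(), (data.I - scale * I_m) / data.sigma
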