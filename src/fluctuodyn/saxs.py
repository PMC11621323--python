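"""Small-angle structure-factor decomposition.

The total SAXS structure factor of the solution is modelled as the sum of a
"normal liquid" component, described by the analytic Percus-Yevick (PY)
hard-sphere structure factor, and an "anomalous" component due to critical
density fluctuations, described by the Ornstein-Zernike (OZ) Lorentzian:

    S(q) = S_PY(q; R, η) + S_A(0) / (1 + ξ² q²)

Fitting the decomposition over the small-angle window (default
0.15 < q < 0.7 Å⁻¹, with the hard-sphere radius fixed at R = 1.78 Å) yields
the packing fraction η, the anomalous amplitude S_A(0) and the correlation
length ξ, and by extrapolation the q → 0 structure factor

    S(0) = S_A(0) + S_PY(0; R, η),

which feeds the isothermal-compressibility estimate.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from lmfit import Minimizer, Parameters

from .constants import DEFAULT_HARD_SPHERE_RADIUS
from .datatypes import SAXSDecomposition, StructureFactorCurve
from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

__all__ = [
    "percus_yevick_sq",
    "percus_yevick_s0",
    "ornstein_zernike",
    "saxs_model",
    "fit_saxs",
    "extrapolate_S0",
]

# Taylor coefficients (in x = 2qR) of the three PY bracket functions. The
# closed forms cancel catastrophically at small x (the f3 bracket is an
# O(x⁶) residue of O(1) terms), so the series is used below x = 0.2, where
# the truncated expansion is accurate to ~1e-12 relative and the closed
# form has recovered full precision.
_SMALL_X = 0.2
_F1_SERIES = (1 / 3, -1 / 30, 1 / 840, -1 / 45360)
_F2_SERIES = (1 / 4, -1 / 36, 1 / 960, -1 / 50400)
_F3_SERIES = (1 / 6, -1 / 48, 1 / 1200, -1 / 60480)


def _poly_small_x(x2, c0, c2, c4, c6):
    return c0 + x2 * (c2 + x2 * (c4 + x2 * c6))


def percus_yevick_sq(q, R: float, eta: float):
    """Analytic Percus-Yevick structure factor of hard spheres.

    Wertheim/Thiele closed-form solution for spheres of radius ``R``
    (diameter 2R) at packing fraction ``eta``; S = 1/(1 - ρ c(q)) with the
    analytic direct-correlation function. Continuous at q → 0 (a series
    expansion replaces the closed form at small 2qR to avoid catastrophic
    cancellation).

    Parameters
    ----------
    q : float or array, Å⁻¹ (q ≥ 0 allowed; the q → 0 limit is finite)
    R : hard-sphere radius, Å
    eta : packing fraction in [0, 0.74)
    """
    if R <= 0:
        raise InvalidParameterError("hard-sphere radius must be positive")
    if not (0 <= eta < 0.74):
        raise InvalidParameterError(f"eta={eta} outside [0, 0.74)")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise InvalidParameterError("q must be non-negative")
    if eta == 0:
        return np.ones_like(q) if q.ndim else 1.0

    one_m = (1 - eta) ** 4
    alpha = (1 + 2 * eta) ** 2 / one_m
    beta = -6 * eta * (1 + eta / 2) ** 2 / one_m
    gamma = eta * alpha / 2

    x = 2.0 * R * q
    x2 = x * x
    small = x < _SMALL_X
    # guard against division by zero on the small-x branch
    xs = np.where(small, 1.0, x)
    sin_x, cos_x = np.sin(xs), np.cos(xs)
    f1 = np.where(small, _poly_small_x(x2, *_F1_SERIES),
                  (sin_x - xs * cos_x) / xs ** 3)
    f2 = np.where(small, _poly_small_x(x2, *_F2_SERIES),
                  (2 * xs * sin_x + (2 - xs ** 2) * cos_x - 2) / xs ** 4)
    f3 = np.where(small, _poly_small_x(x2, *_F3_SERIES),
                  (-xs ** 4 * cos_x
                   + 4 * ((3 * xs ** 2 - 6) * cos_x + (xs ** 3 - 6 * xs) * sin_x + 6))
                  / xs ** 6)
    rho_c = -24 * eta * (alpha * f1 + beta * f2 + gamma * f3)
    S = 1.0 / (1.0 - rho_c)
    return S if S.ndim else float(S)


def percus_yevick_s0(eta: float) -> float:
    """PY compressibility-route q → 0 limit, (1-η)⁴/(1+2η)²."""
    if not (0 <= eta < 0.74):
        raise InvalidParameterError(f"eta={eta} outside [0, 0.74)")
    return (1 - eta) ** 4 / (1 + 2 * eta) ** 2


def ornstein_zernike(q, SA0: float, xi: float):
    """Ornstein-Zernike Lorentzian S_A(q) = S_A(0) / (1 + ξ²q²)."""
    if SA0 < 0:
        raise InvalidParameterError("SA0 must be non-negative")
    if xi < 0:
        raise InvalidParameterError("xi must be non-negative")
    q = np.asarray(q, dtype=float)
    out = SA0 / (1.0 + xi ** 2 * q ** 2)
    return out if out.ndim else float(out)


def saxs_model(q, R: float, eta: float, SA0: float, xi: float):
    """Total SAXS model S_PY(q; R, η) + S_A(0)/(1 + ξ²q²).

    This single implementation is shared by the synthetic curve generator
    and the fitter, so noiseless generated curves are reproduced exactly.
    """
    return percus_yevick_sq(q, R, eta) + ornstein_zernike(q, SA0, xi)


def fit_saxs(
    curve: StructureFactorCurve,
    window: Tuple[float, float] = (0.15, 0.7),
    fix_R: Optional[float] = DEFAULT_HARD_SPHERE_RADIUS,
) -> SAXSDecomposition:
    """Fit the normal + anomalous decomposition to a SAXS curve.

    Weighted nonlinear least squares over (η, S_A(0), ξ) — and R too when
    ``fix_R`` is None — restricted to the fit window. Weights are uniform
    unless the curve carries per-point standard errors. Multi-start over ξ
    avoids the flat S_A(0) ≈ 0 valley; the best-residual solution wins.

    Raises
    ------
    InsufficientDataError : fewer than 8 points in the window.
    FitFailureError : the optimizer failed on every start.
    """
    lo, hi = window
    mask = (curve.q > lo) & (curve.q < hi)
    if mask.sum() < 8:
        raise InsufficientDataError(
            f"need ≥ 8 points in window ({lo}, {hi}), got {int(mask.sum())}"
        )
    q = curve.q[mask]
    S = curve.S[mask]
    if curve.stderr is not None and np.all(curve.stderr[mask] > 0):
        weights = 1.0 / curve.stderr[mask]
    else:
        weights = np.ones_like(q)

    def residual(params):
        p = params.valuesdict()
        return weights * (saxs_model(q, p["R"], p["eta"], p["SA0"], p["xi"]) - S)

    def run_fit(xi_start: float, fix_sa0: bool):
        params = Parameters()
        params.add("R", value=fix_R if fix_R is not None else DEFAULT_HARD_SPHERE_RADIUS,
                   min=0.5, max=5.0, vary=fix_R is None)
        params.add("eta", value=0.35, min=0.0, max=0.74)
        params.add("SA0", value=0.0 if fix_sa0 else max(float(S[0] - S[-1]), 0.01),
                   min=0.0, max=5.0, vary=not fix_sa0)
        params.add("xi", value=xi_start, min=0.0, max=100.0, vary=not fix_sa0)
        try:
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                return Minimizer(residual, params).least_squares()
        except Exception:
            return None

    best = None
    for xi_start in (1.0, 3.0, 10.0):
        result = run_fit(xi_start, fix_sa0=False)
        if result is not None and result.success and (
                best is None or result.chisqr < best.chisqr):
            best = result
    if best is None:
        raise FitFailureError(
            "SAXS decomposition fit did not converge",
            initial_values={"eta": 0.35, "xi": [1.0, 3.0, 10.0]},
        )

    # model comparison against the anomalous-free branch: when pinning
    # SA0 = 0 fits just as well, xi is unidentifiable and the anomalous
    # component is declared absent
    constrained = run_fit(0.0, fix_sa0=True)
    absent = (constrained is not None and constrained.success
              and constrained.chisqr <= best.chisqr * (1 + 1e-3) + 1e-20)
    if absent:
        best = constrained

    p = best.params
    stderrs = {name: (p[name].stderr if p[name].stderr is not None else np.nan)
               for name in ("R", "eta", "SA0", "xi")}
    sa0 = float(p["SA0"].value)
    xi = float(p["xi"].value)
    if absent:
        sa0, xi = 0.0, 0.0
    decomp = SAXSDecomposition(
        R=float(p["R"].value),
        eta=float(p["eta"].value),
        SA0=sa0,
        xi=xi,
        fit_window=(lo, hi),
        S0_total=sa0 + percus_yevick_s0(float(p["eta"].value)),
        parameter_stderrs=stderrs,
        residual_norm=float(np.sqrt(best.chisqr)),
        anomalous_component_absent=absent,
    )
    return decomp


def extrapolate_S0(decomp: SAXSDecomposition) -> Tuple[float, float]:
    """q → 0 extrapolation S(0) = S_A(0) + S_PY(0; R, η) with propagated stderr.

    Error propagation uses dS_PY(0)/dη of the closed form and the fitted
    standard errors of S_A(0) and η (covariances neglected).
    """
    s0 = decomp.SA0 + percus_yevick_s0(decomp.eta)
    eta = decomp.eta
    # d/dη [(1-η)⁴ (1+2η)⁻²]
    dpy = (-4 * (1 - eta) ** 3 * (1 + 2 * eta) ** 2
           - 4 * (1 + 2 * eta) * (1 - eta) ** 4) / (1 + 2 * eta) ** 4
    se_sa0 = decomp.parameter_stderrs.get("SA0", np.nan)
    se_eta = decomp.parameter_stderrs.get("eta", np.nan)
    stderr = float(np.sqrt(np.nan_to_num(se_sa0) ** 2
                           + (dpy * np.nan_to_num(se_eta)) ** 2))
    return float(s0), stderr
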