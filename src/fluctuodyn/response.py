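"""Thermodynamic response functions and critical power-law fits.

Two routes to the isothermal compressibility are implemented:

* scattering route: κ_T = S(0) / (n k_B T), with n the average molecular
  number density of the solution;
* fluctuation route: κ_T = ⟨δV²⟩_NPT / (k_B ⟨V⟩ ⟨T⟩) from an NPT volume
  time series (population variance, matching the ensemble average).

Both are stored in SI (Pa⁻¹); the field's display unit is 10⁻⁶ bar⁻¹
(divide by ``constants.BAR_INV_MICRO``).

The apparent critical behavior on cooling is quantified by power laws

    κ_T(T) = κ_{T,0} ε^{-γ},   ξ(T) = ξ₀ ε^{-ν},   ε = (T − T_s)/T_s,

fitted by full nonlinear least squares with the divergence temperature T_s
free (multi-start, since the objective is multimodal in T_s). An R²
exclusion scan refits while dropping the lowest-temperature points to flag
a deviation from the power law — the signature of approaching a locus of
response-function maxima (Widom line) rather than a critical divergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lmfit import Minimizer, Parameters

from .constants import BAR_INV_MICRO, INV_A3_TO_INV_M3, K_B, M_GLYCEROL, M_WATER, N_A
from .datatypes import PowerLawFit, VolumeSeries
from .errors import FitFailureError, InsufficientDataError, InvalidParameterError

__all__ = [
    "mole_to_weight_fraction",
    "weight_to_mole_fraction",
    "number_density",
    "compressibility_from_S0",
    "kappa_from_volume_fluctuations",
    "powerlaw_model",
    "fit_powerlaw",
    "exclusion_scan",
    "ExclusionScan",
    "exponent_ratio",
    "kappa_to_micro_bar",
]


def mole_to_weight_fraction(chi_g: float, M_g: float = M_GLYCEROL,
                            M_w: float = M_WATER) -> float:
    """Glycerol weight fraction from its mole fraction."""
    if not (0 <= chi_g <= 1):
        raise InvalidParameterError("mole fraction must lie in [0, 1]")
    if M_g <= 0 or M_w <= 0:
        raise InvalidParameterError("molar masses must be positive")
    return chi_g * M_g / (chi_g * M_g + (1 - chi_g) * M_w)


def weight_to_mole_fraction(w_g: float, M_g: float = M_GLYCEROL,
                            M_w: float = M_WATER) -> float:
    """Glycerol mole fraction from its weight fraction (inverse map)."""
    if not (0 <= w_g <= 1):
        raise InvalidParameterError("weight fraction must lie in [0, 1]")
    return (w_g / M_g) / (w_g / M_g + (1 - w_g) / M_w)


def number_density(mass_density: float, comp) -> float:
    """Average molecular number density n in Å⁻³.

    n = ρ N_A / M̄ with the mole-fraction-weighted mean molar mass
    M̄ = χ_g M_g + (1 − χ_g) M_w; ``mass_density`` in g/cm³.
    """
    if mass_density <= 0:
        raise InvalidParameterError("mass density must be positive")
    n_per_cm3 = mass_density * N_A / comp.mean_molar_mass
    return n_per_cm3 * 1e-24  # cm⁻³ → Å⁻³


def compressibility_from_S0(S0: float, n: float, T: float) -> float:
    """Isothermal compressibility κ_T = S(0)/(n k_B T) in Pa⁻¹.

    ``n`` in molecules/Å³ (converted internally to m⁻³), ``T`` in K.
    """
    if S0 <= 0 or n <= 0 or T <= 0:
        raise InvalidParameterError("S0, n and T must all be positive")
    return S0 / (n * INV_A3_TO_INV_M3 * K_B * T)


def kappa_from_volume_fluctuations(series: VolumeSeries) -> float:
    """κ_T = ⟨δV²⟩/(k_B ⟨V⟩ ⟨T⟩) from an NPT volume series, in Pa⁻¹.

    Population (1/N) variance; volumes in Å³ are converted to m³. A
    constant series returns exactly 0.
    """
    v = series.volumes
    var = float(np.var(v))  # population variance, Å⁶
    if var == 0.0:
        return 0.0
    mean_v = float(np.mean(v))
    return (var * 1e-60) / (K_B * mean_v * 1e-30 * series.temperature)


def kappa_to_micro_bar(kappa_pa: float) -> float:
    """Display conversion Pa⁻¹ → 10⁻⁶ bar⁻¹."""
    return kappa_pa / BAR_INV_MICRO


def powerlaw_model(T, amplitude: float, exponent: float, T_s: float):
    """value(T) = amplitude ((T − T_s)/T_s)^(−exponent); requires T > T_s."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= T_s):
        raise InvalidParameterError("all temperatures must exceed T_s")
    eps = (T - T_s) / T_s
    return amplitude * eps ** (-exponent)


def _r_squared(y: np.ndarray, y_fit: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_fit) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_powerlaw(
    points,
    quantity: str = "kappa",
    stderr: Optional[Sequence[float]] = None,
) -> PowerLawFit:
    """Nonlinear least-squares fit of the divergence power law.

    ``points`` is a sequence of (T, value) pairs (or (T, value, stderr)
    triples / a DataFrame with columns T, value[, stderr]). All three of
    (amplitude, exponent, T_s) are free; T_s is bounded below min(T) and
    multi-started at min(T) − {5, 15, 30} K. Weighted by 1/stderr when
    provided. A constant series yields an unidentifiable T_s and is
    flagged degenerate.
    """
    if isinstance(points, pd.DataFrame):
        T = points["T"].to_numpy(dtype=float)
        y = points["value"].to_numpy(dtype=float)
        sig = points["stderr"].to_numpy(dtype=float) if "stderr" in points else None
    else:
        arr = [tuple(p) for p in points]
        T = np.array([p[0] for p in arr], dtype=float)
        y = np.array([p[1] for p in arr], dtype=float)
        sig = (np.array([p[2] for p in arr], dtype=float)
               if arr and len(arr[0]) > 2 else None)
    if stderr is not None:
        sig = np.asarray(stderr, dtype=float)
    if T.size < 4:
        raise InsufficientDataError("need ≥ 4 points for a 3-parameter fit")
    if np.unique(T).size != T.size:
        raise InvalidParameterError("temperatures must be distinct")
    if np.any(y <= 0):
        raise InvalidParameterError("power-law values must be positive")
    weights = 1.0 / sig if sig is not None and np.all(sig > 0) else np.ones_like(y)

    T_min = float(np.min(T))
    # degenerate constant series: exponent 0, T_s unidentifiable
    if np.allclose(y, y[0], rtol=1e-12, atol=0):
        return PowerLawFit(
            amplitude=float(y[0]), exponent=0.0, T_s=np.nan, R_squared=1.0,
            stderrs={"amplitude": 0.0, "exponent": np.nan, "T_s": np.nan},
            fitted_quantity=quantity, degenerate=True,
        )

    def residual(params):
        p = params.valuesdict()
        eps = (T - p["T_s"]) / p["T_s"]
        return weights * (p["amplitude"] * eps ** (-p["exponent"]) - y)

    best = None
    for dT in (5.0, 15.0, 30.0):
        params = Parameters()
        params.add("amplitude", value=float(y[np.argmax(T)]), min=1e-300)
        params.add("exponent", value=0.5, min=-10.0, max=10.0)
        params.add("T_s", value=T_min - dT, min=1.0, max=T_min - 1e-3)
        try:
            import warnings
            with warnings.catch_warnings():
                # a perfect (noiseless) fit yields a zero-variance covariance
                warnings.simplefilter("ignore", RuntimeWarning)
                res = Minimizer(residual, params).least_squares(xtol=1e-15,
                                                                ftol=1e-15,
                                                                gtol=1e-15)
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise FitFailureError("power-law fit did not converge",
                              initial_values={"T_s starts": [T_min - 5, T_min - 15,
                                                             T_min - 30]})
    p = best.params
    y_fit = powerlaw_model(T, p["amplitude"].value, p["exponent"].value,
                           p["T_s"].value)
    stderrs = {name: (p[name].stderr if p[name].stderr is not None else np.nan)
               for name in ("amplitude", "exponent", "T_s")}
    return PowerLawFit(
        amplitude=float(p["amplitude"].value),
        exponent=float(p["exponent"].value),
        T_s=float(p["T_s"].value),
        R_squared=_r_squared(y, y_fit),
        stderrs=stderrs,
        fitted_quantity=quantity,
        degenerate=False,
    )


@dataclass
class ExclusionScan:
    """R² of power-law refits after excluding the lowest-T point(s)."""

    table: pd.DataFrame  # columns: n_excluded, excluded_T, R_squared
    deviation_flagged: bool
    margin: float


def exclusion_scan(points, k_exclude: int, quantity: str = "kappa",
                   margin: float = 0.02) -> ExclusionScan:
    """Refit the power law excluding 0…k_exclude lowest-temperature points.

    A deviation from power-law behavior (a bend toward a response-function
    maximum) is flagged when exclusion improves R² by more than ``margin``
    over the all-points fit.
    """
    if isinstance(points, pd.DataFrame):
        df = points.sort_values("T").reset_index(drop=True)
    else:
        arr = [tuple(p) for p in points]
        df = pd.DataFrame({"T": [p[0] for p in arr],
                           "value": [p[1] for p in arr]}).sort_values("T")
        df = df.reset_index(drop=True)
    n = len(df)
    if k_exclude < 0 or k_exclude >= n - 4:
        raise InsufficientDataError(
            f"k_exclude={k_exclude} leaves fewer than 4 points (n={n})"
        )
    rows = []
    for k in range(k_exclude + 1):
        sub = df.iloc[k:]
        fit = fit_powerlaw(sub, quantity=quantity)
        rows.append({
            "n_excluded": k,
            "excluded_T": tuple(df["T"].iloc[:k].tolist()),
            "R_squared": fit.R_squared,
            "exponent": fit.exponent,
            "T_s": fit.T_s,
        })
    table = pd.DataFrame(rows)
    r2_full = table.loc[0, "R_squared"]
    flagged = bool(np.any(table["R_squared"].iloc[1:] - r2_full > margin))
    return ExclusionScan(table, flagged, margin)


def exponent_ratio(fit_xi: PowerLawFit, fit_kappa: PowerLawFit) -> Tuple[float, float]:
    """Ratio ν/γ of correlation-length to compressibility exponents.

    Returns the ratio and its propagated uncertainty (independent errors).
    At an Ising critical point ν/γ = 0.6/1.2 = 0.5; smaller measured
    exponents indicate supercritical (Widom-line) rather than critical
    behavior.
    """
    nu, gamma = fit_xi.exponent, fit_kappa.exponent
    if gamma == 0:
        raise InvalidParameterError("compressibility exponent is zero")
    ratio = nu / gamma
    se_nu = fit_xi.stderrs.get("exponent", np.nan)
    se_gamma = fit_kappa.stderrs.get("exponent", np.nan)
    with np.errstate(invalid="ignore"):
        err = abs(ratio) * np.sqrt((se_nu / nu) ** 2 + (se_gamma / gamma) ** 2) \
            if nu != 0 else np.nan
    return float(ratio), float(err)
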