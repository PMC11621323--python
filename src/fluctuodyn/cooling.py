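"""Knudsen evaporative cooling of binary glycerol-water microdroplets.

A droplet injected into vacuum loses water by free-molecular (Knudsen)
evaporation; the latent heat carried away cools the droplet by tens of
kelvin within milliseconds of flight. Glycerol is treated as non-volatile,
so the glycerol mole fraction rises as water evaporates.

Model (lumped, uniform internal temperature):

    J(T, χ_g)  = α p_vap(T) a_w(χ_g) sqrt(M_w / (2π R T))   [kg m⁻² s⁻¹]
    dm_w/dt    = −4π r² J
    dT/dt      = −J L_vap(T) 4π r² / (m c_p(T, χ_g))

integrated with a fixed-step classical 4th-order Runge-Kutta scheme.
Water activity defaults to Raoult's law, a_w = 1 − χ_g. Radiative exchange
and residual-gas conduction are neglected (chamber pressures of a few Pa).

Thermophysical correlations (all stated here and swappable via the module
attributes):

* saturation vapor pressure of (supercooled) liquid water: Murphy & Koop
  (2005) correlation, used in its stated validity window;
* molar enthalpy of vaporization: Murphy & Koop (2005) polynomial +
  exponential form for supercooled water;
* liquid water heat capacity: empirical fit rising toward deep
  supercooling (≈75 J mol⁻¹ K⁻¹ at 273 K, ≈103 at 228 K); glycerol
  c_p = 2430 J kg⁻¹ K⁻¹, ideal (mass-weighted) mixing;
* mixture density: ideal volume mixing of 1000 and 1261 kg/m³.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .constants import M_GLYCEROL, M_WATER, R_GAS
from .datatypes import DropletState
from .errors import IntegrationAbortError, InvalidParameterError

__all__ = [
    "vapor_pressure_water",
    "latent_heat_water",
    "heat_capacity_mixture",
    "mixture_density",
    "knudsen_flux",
    "integrate_cooling",
    "temperature_at_distance",
]

#: Validity window enforced for the vapor-pressure correlation, K.
VAPOR_PRESSURE_RANGE = (150.0, 320.0)

_M_W_KG = M_WATER * 1e-3  # kg/mol
_RHO_WATER = 1000.0  # kg/m³
_RHO_GLYCEROL = 1261.0  # kg/m³
_CP_GLYCEROL = 2430.0  # J/(kg K)


def vapor_pressure_water(T) -> np.ndarray:
    """Saturation vapor pressure of liquid (incl. supercooled) water, Pa.

    Murphy & Koop (2005) liquid-water correlation.
    """
    T = np.asarray(T, dtype=float)
    lo, hi = VAPOR_PRESSURE_RANGE
    if np.any(T < lo) or np.any(T > hi):
        raise InvalidParameterError(
            f"temperature outside vapor-pressure correlation range {VAPOR_PRESSURE_RANGE}"
        )
    ln_p = (54.842763 - 6763.22 / T - 4.210 * np.log(T) + 0.000367 * T
            + np.tanh(0.0415 * (T - 218.8))
            * (53.878 - 1331.22 / T - 9.44523 * np.log(T) + 0.014025 * T))
    out = np.exp(ln_p)
    return out if out.ndim else float(out)


def latent_heat_water(T) -> np.ndarray:
    """Molar enthalpy of vaporization of supercooled water, J/mol
    (Murphy & Koop 2005), divided by M_w gives J/kg via the caller."""
    T = np.asarray(T, dtype=float)
    out = 56579.0 - 42.212 * T + np.exp(0.1149 * (281.6 - T))
    return out if out.ndim else float(out)


def _cp_water_molar(T) -> np.ndarray:
    # empirical rise of liquid-water c_p toward deep supercooling
    T = np.asarray(T, dtype=float)
    return 74.5 + 28.0 * np.exp(-(T - 228.0) / 15.0)


def heat_capacity_mixture(T, chi_g: float) -> float:
    """Specific heat of the mixture, J/(kg K), ideal mass-weighted mixing."""
    w_g = chi_g * M_GLYCEROL / (chi_g * M_GLYCEROL + (1 - chi_g) * M_WATER)
    cp_w = _cp_water_molar(T) / _M_W_KG
    return float((1 - w_g) * cp_w + w_g * _CP_GLYCEROL)


def mixture_density(chi_g: float) -> float:
    """Mixture mass density, kg/m³ (ideal volume mixing, T-independent)."""
    w_g = chi_g * M_GLYCEROL / (chi_g * M_GLYCEROL + (1 - chi_g) * M_WATER)
    return 1.0 / ((1 - w_g) / _RHO_WATER + w_g / _RHO_GLYCEROL)


def knudsen_flux(T: float, chi_g: float, alpha: float = 1.0) -> float:
    """Evaporative mass flux J = α p_vap(T) a_w sqrt(M_w/(2π R T)), kg m⁻² s⁻¹.

    Free-molecular (Knudsen) effusion with evaporation coefficient ``alpha``
    (default 1, the Knudsen-limit assumption) and Raoult water activity
    a_w = 1 − χ_g.
    """
    if not (0 <= chi_g <= 1):
        raise InvalidParameterError("chi_g must lie in [0, 1]")
    if alpha < 0:
        raise InvalidParameterError("alpha must be non-negative")
    p = vapor_pressure_water(T)
    a_w = 1.0 - chi_g
    return float(alpha * p * a_w * np.sqrt(_M_W_KG / (2.0 * np.pi * R_GAS * T)))


def _split_masses(state: DropletState):
    w_g = state.chi_g * M_GLYCEROL / (state.chi_g * M_GLYCEROL
                                      + (1 - state.chi_g) * M_WATER)
    m_g = state.mass * w_g
    return state.mass - m_g, m_g


def _chi_from_masses(m_w: float, m_g: float) -> float:
    n_w = m_w / M_WATER
    n_g = m_g / M_GLYCEROL
    return n_g / (n_w + n_g)


def _radius_m(mass: float, chi_g: float) -> float:
    volume = mass / mixture_density(chi_g)
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def make_droplet(diameter_um: float, chi_g: float,
                 temperature: float = 293.15) -> DropletState:
    """Initial droplet state from diameter (μm) and glycerol mole fraction."""
    if diameter_um <= 0:
        raise InvalidParameterError("diameter must be positive")
    r = diameter_um * 1e-6 / 2.0
    mass = mixture_density(chi_g) * (4.0 / 3.0) * np.pi * r ** 3
    return DropletState(0.0, diameter_um / 2.0, temperature, chi_g, mass)


def integrate_cooling(
    initial: DropletState,
    duration: float,
    step: float = 1e-6,
    alpha: float = 1.0,
) -> List[DropletState]:
    """Integrate the coupled mass/energy balance with fixed-step RK4.

    Glycerol is non-volatile: its mass is constant and χ_g rises as water
    leaves. Aborts with IntegrationAbortError (carrying the last valid
    state) if the state turns nonphysical.
    """
    if step <= 0 or duration < 0:
        raise InvalidParameterError("duration and step must be positive")
    m_w0, m_g = _split_masses(initial)

    def derivs(m_w: float, T: float):
        if m_w <= 0 or T <= 0:
            raise IntegrationAbortError("nonphysical state during integration")
        chi = _chi_from_masses(m_w, m_g)
        m = m_w + m_g
        r = _radius_m(m, chi)
        area = 4.0 * np.pi * r ** 2
        J = knudsen_flux(T, chi, alpha=alpha)
        dm_w = -area * J
        L_mass = latent_heat_water(T) / _M_W_KG  # J/kg
        dT = -J * L_mass * area / (m * heat_capacity_mixture(T, chi))
        return dm_w, dT

    n_steps = int(round(duration / step))
    t, m_w, T = initial.time, m_w0, initial.temperature
    traj = [DropletState(t, _radius_m(m_w + m_g, initial.chi_g) * 1e6,
                         T, initial.chi_g, m_w + m_g)]
    for _ in range(n_steps):
        try:
            k1m, k1t = derivs(m_w, T)
            k2m, k2t = derivs(m_w + 0.5 * step * k1m, T + 0.5 * step * k1t)
            k3m, k3t = derivs(m_w + 0.5 * step * k2m, T + 0.5 * step * k2t)
            k4m, k4t = derivs(m_w + step * k3m, T + step * k3t)
        except (IntegrationAbortError, InvalidParameterError) as exc:
            raise IntegrationAbortError(
                f"integration aborted at t={t:.3e} s: {exc}", last_state=traj[-1]
            ) from exc
        m_w += step * (k1m + 2 * k2m + 2 * k3m + k4m) / 6.0
        T += step * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0
        t += step
        if m_w <= 0 or T <= 0:
            raise IntegrationAbortError(
                f"nonphysical state reached at t={t:.3e} s", last_state=traj[-1]
            )
        chi = _chi_from_masses(m_w, m_g)
        traj.append(DropletState(t, _radius_m(m_w + m_g, chi) * 1e6,
                                 T, chi, m_w + m_g))
    return traj


def temperature_at_distance(
    trajectory: Sequence[DropletState],
    jet_speed: float,
    distance_mm: float,
) -> float:
    """Droplet temperature at a given flight distance (mm) and jet speed (m/s).

    Linear interpolation of T at time = distance / jet_speed; distances
    beyond the integrated trajectory raise an error.
    """
    if jet_speed <= 0:
        raise InvalidParameterError("jet speed must be positive")
    if distance_mm < 0:
        raise InvalidParameterError("distance must be non-negative")
    t_target = distance_mm * 1e-3 / jet_speed
    times = np.array([s.time for s in trajectory])
    temps = np.array([s.temperature for s in trajectory])
    if t_target > times[-1] or t_target < times[0]:
        raise InvalidParameterError(
            f"distance {distance_mm} mm maps to t={t_target:.3e} s, outside the "
            f"trajectory range [{times[0]:.3e}, {times[-1]:.3e}] s"
        )
    return float(np.interp(t_target, times, temps))
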