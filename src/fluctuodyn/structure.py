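"""Real-space pair correlations and reciprocal-space structure factors.

The pipeline step implemented here goes from a periodic particle
configuration to g(r) (minimum-image pair histogram over heavy atoms), then
to S(q) by a windowed Fourier transform

    S(q) ≈ 1 + 4πρ̄ ∫₀^{r_max} w(r) r [g(r) − 1] sin(qr)/q dr,

with r_max = min(box)/2 and a window function w(r) that suppresses
truncation ripples. Wide-angle observables (first-peak position q₁(T), its
temperature derivative, and the isosbestic point of a family of curves) are
extracted from S(q) curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from lmfit import Minimizer, Parameters
from scipy.interpolate import make_smoothing_spline
from scipy.spatial import cKDTree

from .datatypes import (
    Configuration,
    PeakPosition,
    RadialDistributionFunction,
    StructureFactorCurve,
)
from .errors import (
    FitFailureError,
    IncompatibleGridsError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "compute_rdf",
    "window_function",
    "rdf_to_structure_factor",
    "fit_first_peak",
    "q1_derivative_maximum",
    "find_isosbestic",
    "DerivativeMaximum",
    "IsosbesticPoint",
]

#: Species excluded from g(r) by default: hydrogens contribute negligibly to
#: the X-ray scattering cross-section compared to O/C.
DEFAULT_EXCLUDED_SPECIES = frozenset({"H"})


def _minimum_image_distances(pos_i: np.ndarray, pos_j: np.ndarray,
                             box: np.ndarray) -> np.ndarray:
    d = pos_i - pos_j
    d -= box * np.round(d / box)
    return np.sqrt(np.sum(d * d, axis=-1))


def compute_rdf(
    config: Configuration,
    species_filter: Optional[Iterable[str]] = None,
    bin_width: float = 0.02,
) -> RadialDistributionFunction:
    """Minimum-image radial distribution function of the filtered particles.

    Parameters
    ----------
    config : periodic configuration (orthorhombic box).
    species_filter : labels to keep. Default: every species except "H"
        (heavy atoms are treated as a single indistinguishable set; no
        per-element form-factor weighting).
    bin_width : histogram bin width in Å.

    The histogram extends to r_max = min(box)/2 and is normalized by the
    ideal-gas shell counts at the density ρ̄ of the filtered set.
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    if species_filter is None:
        keep = [s for s in np.unique(config.species) if s not in DEFAULT_EXCLUDED_SPECIES]
    else:
        keep = list(species_filter)
    sub = config.select(keep)
    n = sub.n_particles
    if n < 2:
        raise InsufficientDataError(f"need ≥ 2 particles after filtering, got {n}")

    box = sub.box
    r_max = float(np.min(box)) / 2.0
    n_bins = int(np.floor(r_max / bin_width))
    if n_bins < 1:
        raise InvalidParameterError("bin_width larger than half the box")
    edges = np.arange(n_bins + 1) * bin_width
    r_max_hist = edges[-1]

    tree = cKDTree(sub.positions, boxsize=box)
    pairs = tree.query_pairs(r_max_hist, output_type="ndarray")
    if pairs.size:
        dists = _minimum_image_distances(sub.positions[pairs[:, 0]],
                                         sub.positions[pairs[:, 1]], box)
        counts, _ = np.histogram(dists, bins=edges)
    else:
        counts = np.zeros(n_bins)

    rho = n / sub.volume
    shell_volumes = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    # each unordered pair counted once → expected ideal count per bin is
    # N ρ V_shell / 2
    ideal = 0.5 * n * rho * shell_volumes
    g = counts / ideal
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialDistributionFunction(centers, g, rho, r_max)


def window_function(r, r_max: float):
    """Truncation window for the g(r) → S(q) Fourier transform.

    Piecewise:  1 − 3(r/r_max)²                      for r < r_max/3,
                (3/2)[1 − 2r/r_max + (r/r_max)²]     for r_max/3 ≤ r ≤ r_max,
                0                                    for r > r_max.
    Continuous on [0, r_max], equal to 2/3 at r_max/3 and to 0 at r_max.
    """
    if r_max <= 0:
        raise InvalidParameterError("r_max must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("r must be non-negative")
    x = r / r_max
    w = np.where(
        x < 1.0 / 3.0,
        1.0 - 3.0 * x ** 2,
        np.where(x <= 1.0, 1.5 * (1.0 - 2.0 * x + x ** 2), 0.0),
    )
    return w if w.ndim else float(w)


def rdf_to_structure_factor(
    rdf: RadialDistributionFunction,
    q_grid: Sequence[float],
    temperature: Optional[float] = None,
) -> StructureFactorCurve:
    """Windowed Fourier transform of g(r) to S(q).

    Trapezoidal quadrature on the g(r) bin centers. The q = 0 limit is not
    handled here (extrapolate S(0) from a SAXS decomposition instead).
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise InvalidParameterError("q grid must be strictly positive (q=0 is a limit, "
                                    "handled by S(0) extrapolation)")
    r = rdf.r_centers
    w = window_function(r, rdf.r_max)
    kernel = w * r * (rdf.g_values - 1.0)  # shape (n_r,)
    qr = np.outer(q, r)
    integrand = kernel[None, :] * np.sin(qr) / q[:, None]
    S = 1.0 + 4.0 * np.pi * rdf.number_density * np.trapezoid(integrand, r, axis=1)
    return StructureFactorCurve(q, S, temperature=temperature, provenance="simulation")


def _gaussian_baseline(q, amplitude, center, width, baseline):
    return baseline + amplitude * np.exp(-0.5 * ((q - center) / width) ** 2)


def fit_first_peak(
    curve: StructureFactorCurve,
    window: Tuple[float, float] = (1.7, 1.9),
) -> PeakPosition:
    """Gaussian + constant-baseline fit of the first diffraction peak.

    Initialization: center at the argmax inside the window (ties toward
    lower q), width = window/4, baseline = window minimum. Returns the
    fitted center and its standard error. A window without a peak (monotone
    data pushing the center out of the window) raises FitFailureError.
    """
    lo, hi = window
    mask = (curve.q >= lo) & (curve.q <= hi)
    if mask.sum() < 5:
        raise InsufficientDataError(
            f"need ≥ 5 points in window ({lo}, {hi}), got {int(mask.sum())}"
        )
    q, S = curve.q[mask], curve.S[mask]
    c0 = float(q[np.argmax(S)])
    a0 = float(np.max(S) - np.min(S)) or 1e-3
    w0 = (hi - lo) / 4.0
    b0 = float(np.min(S))
    params = Parameters()
    params.add("amplitude", value=a0, min=0.0)
    params.add("center", value=c0)
    params.add("width", value=w0, min=1e-6)
    params.add("baseline", value=b0)

    def residual(p):
        v = p.valuesdict()
        return _gaussian_baseline(q, v["amplitude"], v["center"], v["width"],
                                  v["baseline"]) - S

    result = Minimizer(residual, params).least_squares()
    v = result.params
    center = float(v["center"].value)
    if not result.success or not (lo < center < hi):
        raise FitFailureError(
            "no peak found inside the fit window",
            initial_values={"amplitude": a0, "center": c0, "width": w0, "baseline": b0},
            residual_norm=float(np.sqrt(result.chisqr)) if result.chisqr else None,
        )
    stderr = v["center"].stderr if v["center"].stderr is not None else 0.0
    return PeakPosition(
        q1=center,
        q1_stderr=float(stderr),
        fit_window=(lo, hi),
        gaussian_params=(float(v["amplitude"].value), center,
                         float(v["width"].value), float(v["baseline"].value)),
    )


@dataclass
class DerivativeMaximum:
    """Location of the maximum of dq₁/dT from a smoothing-spline fit."""

    T_max: float  # K
    T_grid: np.ndarray
    dq1_dT: np.ndarray
    unique: bool  # False when the derivative is flat (e.g. linear q₁(T))


def q1_derivative_maximum(
    series: Sequence[Tuple[float, object]],
    lam: Optional[float] = None,
    n_dense: int = 2001,
) -> DerivativeMaximum:
    """Maximum of dq₁/dT from a smoothing spline of q₁(T).

    ``series`` is a sequence of (T, PeakPosition) or (T, q1 value) pairs
    sorted by strictly increasing temperature. The smoothing parameter is
    chosen by generalized cross-validation unless ``lam`` is given.
    """
    if len(series) < 5:
        raise InsufficientDataError("need ≥ 5 temperatures for the derivative maximum")
    T = np.array([t for t, _ in series], dtype=float)
    if np.any(np.diff(T) <= 0):
        raise InvalidParameterError("temperatures must be strictly increasing")
    q1 = np.array([p.q1 if hasattr(p, "q1") else float(p) for _, p in series])
    spl = make_smoothing_spline(T, q1, lam=lam)
    T_dense = np.linspace(T[0], T[-1], n_dense)
    deriv = spl.derivative()(T_dense)
    span = float(np.max(deriv) - np.min(deriv))
    scale = max(float(np.max(np.abs(deriv))), 1e-30)
    unique = span > 1e-6 * scale
    if not unique:
        warnings.warn("dq1/dT is constant within tolerance; maximum is not unique")
    idx = int(np.argmax(deriv))
    return DerivativeMaximum(float(T_dense[idx]), T_dense, deriv, unique)


@dataclass
class IsosbesticPoint:
    """Common crossing point of a temperature family of S(q) curves."""

    q_iso: float  # Å⁻¹
    q_grid: np.ndarray
    variance: np.ndarray  # across-temperature variance of S(q)
    unique: bool


def find_isosbestic(curves: Sequence[StructureFactorCurve]) -> IsosbesticPoint:
    """Wavevector minimizing the across-temperature variance of S(q).

    Curves are linearly interpolated onto the overlap section of the first
    curve's q grid. Identical curves (variance zero everywhere) are flagged
    non-unique.
    """
    if len(curves) < 3:
        raise InsufficientDataError("need ≥ 3 curves to locate an isosbestic point")
    lo = max(float(c.q[0]) for c in curves)
    hi = min(float(c.q[-1]) for c in curves)
    if lo >= hi:
        raise IncompatibleGridsError("curves have disjoint q ranges")
    base = curves[0].q
    grid = base[(base >= lo) & (base <= hi)]
    if grid.size < 3:
        grid = np.linspace(lo, hi, 101)
    stack = np.vstack([np.interp(grid, c.q, c.S) for c in curves])
    var = np.var(stack, axis=0)
    scale = max(float(np.max(var)), 1e-300)
    unique = (np.max(var) - np.min(var)) > 1e-9 * scale and np.max(var) > 1e-24
    if not unique:
        warnings.warn("S(q) curves are identical within tolerance; "
                      "isosbestic point is not unique")
    idx = int(np.argmin(var))
    return IsosbesticPoint(float(grid[idx]), grid, var, unique)
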