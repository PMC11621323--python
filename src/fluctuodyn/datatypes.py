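"""Core data containers shared by the analysis stages.

All containers are plain dataclasses with eager validation: a constructed
instance satisfies its physical invariants (positive box lengths, strictly
increasing grids, matching array lengths, ...). Arrays are stored as
``numpy.ndarray`` of float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .errors import InvalidParameterError, UnsupportedGeometryError

__all__ = [
    "Configuration",
    "RadialDistributionFunction",
    "StructureFactorCurve",
    "PeakPosition",
    "SAXSDecomposition",
    "PowerLawFit",
    "MixtureComposition",
    "CompressibilityPoint",
    "VolumeSeries",
    "LSIRecord",
    "PopulationFractions",
    "DropletState",
]


def _as_float_array(x, name: str, ndim: int = 1) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise InvalidParameterError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{name} contains non-finite values")
    return arr


@dataclass
class Configuration:
    """Particles in a periodic orthorhombic box.

    Attributes
    ----------
    box : (3,) array, Å
        Edge lengths of the orthorhombic cell.
    positions : (N, 3) array, Å
        Particle coordinates; wrapped into [0, box) on construction.
    species : (N,) array of str
        Per-particle element/species labels (e.g. "O", "H", "C").
    temperature : float or None, K
        Optional thermodynamic metadata.
    """

    box: np.ndarray
    positions: np.ndarray
    species: np.ndarray
    temperature: Optional[float] = None

    def __post_init__(self):
        self.box = _as_float_array(self.box, "box")
        if self.box.shape != (3,):
            raise UnsupportedGeometryError(
                f"box must be three orthorhombic edge lengths, got shape {self.box.shape}"
            )
        if np.any(self.box <= 0):
            raise InvalidParameterError("box lengths must be positive")
        self.positions = _as_float_array(self.positions, "positions", ndim=2)
        if self.positions.shape[1] != 3:
            raise InvalidParameterError("positions must be an (N, 3) array")
        # wrap into the primary cell
        self.positions = np.mod(self.positions, self.box)
        self.species = np.asarray(self.species, dtype=str)
        if self.species.shape[0] != self.positions.shape[0]:
            raise InvalidParameterError("species list must match positions length")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return float(np.prod(self.box))

    def select(self, labels) -> "Configuration":
        """Sub-configuration containing only the given species labels."""
        mask = np.isin(self.species, list(labels))
        return Configuration(self.box.copy(), self.positions[mask], self.species[mask],
                             self.temperature)


@dataclass
class RadialDistributionFunction:
    """Binned pair correlation g(r) of a filtered particle set."""

    r_centers: np.ndarray  # Å
    g_values: np.ndarray  # dimensionless
    number_density: float  # Å⁻³
    r_max: float  # Å

    def __post_init__(self):
        self.r_centers = _as_float_array(self.r_centers, "r_centers")
        self.g_values = _as_float_array(self.g_values, "g_values")
        if self.r_centers.shape != self.g_values.shape:
            raise InvalidParameterError("r_centers and g_values must have equal length")
        if np.any(np.diff(self.r_centers) <= 0):
            raise InvalidParameterError("r_centers must be strictly increasing")
        if np.any(self.g_values < 0):
            raise InvalidParameterError("g(r) must be non-negative")
        if self.number_density <= 0:
            raise InvalidParameterError("number density must be positive")
        if self.r_max <= 0:
            raise InvalidParameterError("r_max must be positive")


@dataclass
class StructureFactorCurve:
    """Static structure factor S(q) at one temperature."""

    q: np.ndarray  # Å⁻¹, strictly increasing, > 0
    S: np.ndarray  # dimensionless
    temperature: Optional[float] = None  # K
    provenance: str = "synthetic"  # {"experiment", "simulation", "synthetic"}
    stderr: Optional[np.ndarray] = None

    def __post_init__(self):
        self.q = _as_float_array(self.q, "q")
        self.S = _as_float_array(self.S, "S")
        if self.q.shape != self.S.shape:
            raise InvalidParameterError("q and S must have equal length")
        if np.any(self.q <= 0):
            raise InvalidParameterError("q grid must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise InvalidParameterError("q grid must be strictly increasing")
        if self.provenance not in ("experiment", "simulation", "synthetic"):
            raise InvalidParameterError(f"unknown provenance {self.provenance!r}")
        if self.stderr is not None:
            self.stderr = _as_float_array(self.stderr, "stderr")
            if self.stderr.shape != self.q.shape:
                raise InvalidParameterError("stderr must match q length")


@dataclass
class PeakPosition:
    """First-diffraction-peak position from a Gaussian fit."""

    q1: float  # Å⁻¹
    q1_stderr: float  # Å⁻¹
    fit_window: Tuple[float, float]  # Å⁻¹
    gaussian_params: Tuple[float, float, float, float]  # amplitude, center, width, baseline

    def __post_init__(self):
        lo, hi = self.fit_window
        if not (lo < self.q1 < hi):
            raise InvalidParameterError(
                f"fitted center {self.q1} outside window ({lo}, {hi})"
            )
        if self.q1_stderr < 0:
            raise InvalidParameterError("q1 stderr must be non-negative")


@dataclass
class SAXSDecomposition:
    """Split of a SAXS structure factor into normal (hard-sphere) and
    anomalous (Ornstein-Zernike) components."""

    R: float  # hard-sphere radius, Å
    eta: float  # packing fraction
    SA0: float  # anomalous amplitude at q = 0
    xi: float  # correlation length, Å
    fit_window: Tuple[float, float]
    S0_total: float
    parameter_stderrs: dict = field(default_factory=dict)
    residual_norm: float = np.nan
    anomalous_component_absent: bool = False

    def __post_init__(self):
        if not (0 <= self.eta < 0.74):
            raise InvalidParameterError(f"eta={self.eta} outside [0, 0.74)")
        if self.xi < 0:
            raise InvalidParameterError("xi must be non-negative")
        if self.SA0 < 0:
            raise InvalidParameterError("SA0 must be non-negative")


@dataclass
class PowerLawFit:
    """Power-law divergence fit value(T) = amplitude * ((T - T_s)/T_s)^(-exponent)."""

    amplitude: float
    exponent: float
    T_s: float  # K
    R_squared: float
    stderrs: dict = field(default_factory=dict)
    fitted_quantity: str = "kappa"  # {"kappa", "xi"}
    degenerate: bool = False

    def __post_init__(self):
        if self.fitted_quantity not in ("kappa", "xi"):
            raise InvalidParameterError(f"unknown fitted quantity {self.fitted_quantity!r}")
        if self.R_squared > 1 + 1e-12:
            raise InvalidParameterError("R² cannot exceed 1")


@dataclass
class MixtureComposition:
    """Binary water + glycerol composition with derived densities."""

    mole_fraction_glycerol: float
    molar_mass_water: float = 18.015  # g/mol
    molar_mass_glycerol: float = 92.094  # g/mol
    mass_density: Optional[float] = None  # g/cm³

    def __post_init__(self):
        if not (0 <= self.mole_fraction_glycerol <= 1):
            raise InvalidParameterError("mole fraction must lie in [0, 1]")
        if self.molar_mass_water <= 0 or self.molar_mass_glycerol <= 0:
            raise InvalidParameterError("molar masses must be positive")
        if self.mass_density is not None and self.mass_density <= 0:
            raise InvalidParameterError("mass density must be positive")

    @property
    def weight_fraction(self) -> float:
        chi = self.mole_fraction_glycerol
        mg, mw = self.molar_mass_glycerol, self.molar_mass_water
        return chi * mg / (chi * mg + (1 - chi) * mw)

    @property
    def mean_molar_mass(self) -> float:
        chi = self.mole_fraction_glycerol
        return chi * self.molar_mass_glycerol + (1 - chi) * self.molar_mass_water


@dataclass
class CompressibilityPoint:
    """Isothermal compressibility at one temperature."""

    T: float  # K
    kappa_T: float  # Pa⁻¹
    S0: Optional[float] = None
    n: Optional[float] = None  # molecules/Å³
    stderr: Optional[float] = None  # Pa⁻¹

    def __post_init__(self):
        if self.T <= 0:
            raise InvalidParameterError("temperature must be positive")
        if self.kappa_T < 0:
            raise InvalidParameterError("compressibility must be non-negative")


@dataclass
class VolumeSeries:
    """NPT volume time series."""

    times: np.ndarray  # ps
    volumes: np.ndarray  # Å³
    temperature: float  # K

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.volumes = _as_float_array(self.volumes, "volumes")
        if self.times.shape != self.volumes.shape:
            raise InvalidParameterError("times and volumes must have equal length")
        if self.volumes.size < 2:
            raise InvalidParameterError("need at least 2 volume samples")
        if np.any(self.volumes <= 0):
            raise InvalidParameterError("volumes must be positive")
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be positive")


@dataclass
class LSIRecord:
    """Per-molecule local structure index with its neighbor shell."""

    molecule_index: int
    lsi_value: float  # Å²
    n_neighbors: int
    neighbor_distances: np.ndarray  # Å, sorted ascending, includes first beyond cutoff

    def __post_init__(self):
        if self.lsi_value < 0:
            raise InvalidParameterError("LSI must be non-negative")
        if self.n_neighbors < 1:
            raise InvalidParameterError("need at least one neighbor inside the cutoff")
        self.neighbor_distances = _as_float_array(self.neighbor_distances,
                                                  "neighbor_distances")
        if np.any(np.diff(self.neighbor_distances) < 0):
            raise InvalidParameterError("neighbor distances must be sorted ascending")


@dataclass
class PopulationFractions:
    """HDL-/LDL-like population split at one temperature."""

    T: float  # K
    fraction_hdl: float  # LSI ≤ threshold
    fraction_ldl: float  # LSI > threshold
    threshold: float  # Å²
    n_molecules: int

    def __post_init__(self):
        if abs(self.fraction_hdl + self.fraction_ldl - 1.0) > 1e-9:
            raise InvalidParameterError("HDL and LDL fractions must sum to 1")
        if self.threshold <= 0:
            raise InvalidParameterError("threshold must be positive")


@dataclass
class DropletState:
    """Instantaneous state of an evaporating binary microdroplet."""

    time: float  # s
    radius: float  # μm
    temperature: float  # K
    chi_g: float  # glycerol mole fraction
    mass: float  # kg

    def __post_init__(self):
        if self.radius <= 0 or self.temperature <= 0 or self.mass <= 0:
            raise InvalidParameterError("droplet state must have positive r, T, m")
        if not (0 <= self.chi_g <= 1):
            raise InvalidParameterError("chi_g must lie in [0, 1]")
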