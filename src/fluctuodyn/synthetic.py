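"""Synthetic input generators with known ground truth.

Every pipeline stage can be exercised without external data: homogeneous
(ideal-gas) and hard-sphere configurations with known S(0), water-like
oxygen configurations with a controllable HDL/LDL split, SAXS curves of the
normal + anomalous form with known (R, η, S_A(0), ξ), power-law series, and
Gaussian NPT volume series with a prescribed compressibility.

All generators take an explicit integer seed and use an independent
``numpy.random.default_rng`` — no global state; a fixed seed reproduces the
output bit for bit. Noise models: additive Gaussian on curves,
multiplicative relative Gaussian on power-law series.

The water-like generator is a geometric stand-in, not a water model: the
LDL-like population sits on a diamond-cubic oxygen lattice (nearest
neighbor O-O 2.75 Å, second shell at 4.49 Å — the wide gap the LSI
detects), while the HDL-like population is a denser disordered cluster
(face-centered sites, nearest neighbor 3.0 Å, strong positional disorder)
whose interstitial neighbors fill the first-to-second shell gap.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .constants import K_B
from .datatypes import Configuration, StructureFactorCurve, VolumeSeries
from .errors import InvalidParameterError, PlacementFailureError
from .saxs import saxs_model

__all__ = [
    "generate_ideal_gas",
    "generate_hard_sphere",
    "generate_water_like",
    "generate_saxs_curve",
    "generate_powerlaw_series",
    "generate_volume_series",
]

_DIAMOND_NN = 2.75  # Å, first-shell O-O distance of the tetrahedral lattice
_DIAMOND_A = _DIAMOND_NN * 4.0 / np.sqrt(3.0)  # cubic lattice constant
_FCC_NN = 3.0  # Å, nearest-neighbor distance of the dense (HDL-like) sites
_FCC_A = _FCC_NN * np.sqrt(2.0)
_HDL_DISORDER = 0.25  # Å, built-in Gaussian disorder of the dense cluster


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if value <= 0:
            raise InvalidParameterError(f"{name} must be positive, got {value}")


def generate_ideal_gas(n_particles: int, box: float, seed: int) -> Configuration:
    """Uniform independent positions in [0, box)³ — a Poisson point process.

    The pair correlation of the output is g(r) ≡ 1 (within sampling error),
    hence S(q) ≡ 1.
    """
    if n_particles < 2:
        raise InvalidParameterError("need at least 2 particles")
    _check_positive(box=box)
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.0, box, size=(n_particles, 3))
    return Configuration([box] * 3, pos, ["O"] * n_particles)


def generate_hard_sphere(
    n_particles: int,
    box: float,
    radius: float,
    seed: int,
    n_sweeps: int = 30,
    max_attempts_per_particle: int = 2000,
) -> Configuration:
    """Equilibrated hard-sphere fluid configuration.

    Random sequential insertion (no pair closer than 2·radius under the
    minimum image) followed by ``n_sweeps`` Metropolis displacement sweeps
    to relax toward the equilibrium hard-sphere fluid, whose long-wavelength
    limit is well described by the Percus-Yevick compressibility
    S(0) = (1−η)⁴/(1+2η)².

    Raises PlacementFailureError if the packing fraction is too high to
    place within the attempt budget (pre-check: η ≤ 0.45).
    """
    if n_particles < 1:
        raise InvalidParameterError("need at least 1 particle")
    _check_positive(box=box, radius=radius)
    eta = n_particles * (4.0 / 3.0) * np.pi * radius ** 3 / box ** 3
    if eta > 0.45:
        raise InvalidParameterError(
            f"packing fraction η={eta:.3f} exceeds the insertion limit 0.45"
        )
    rng = np.random.default_rng(seed)
    d_min2 = (2.0 * radius) ** 2
    box3 = np.array([box] * 3)
    pos = np.empty((n_particles, 3))
    n_placed = 0
    attempts = 0
    budget = max_attempts_per_particle * n_particles
    while n_placed < n_particles:
        if attempts > budget:
            raise PlacementFailureError(
                f"placed only {n_placed}/{n_particles} spheres at η={eta:.3f} "
                f"within {budget} attempts"
            )
        trial = rng.uniform(0.0, box, size=3)
        attempts += 1
        if n_placed:
            d = pos[:n_placed] - trial
            d -= box3 * np.round(d / box3)
            if np.min(np.einsum("ij,ij->i", d, d)) < d_min2:
                continue
        pos[n_placed] = trial
        n_placed += 1

    # Metropolis relaxation: random single-particle displacements, rejected
    # on hard-core overlap
    step = 0.5 * radius
    for _ in range(n_sweeps):
        movers = rng.integers(0, n_particles, size=n_particles)
        deltas = rng.uniform(-step, step, size=(n_particles, 3))
        for i, delta in zip(movers, deltas):
            trial = np.mod(pos[i] + delta, box3)
            d = pos - trial
            d -= box3 * np.round(d / box3)
            dist2 = np.einsum("ij,ij->i", d, d)
            dist2[i] = np.inf
            if np.min(dist2) >= d_min2:
                pos[i] = trial
    return Configuration(box3, pos, ["O"] * n_particles)


def _diamond_sites(n_cells: int) -> np.ndarray:
    base = np.array([
        [0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0],
        [0.25, 0.25, 0.25], [0.25, 0.75, 0.75],
        [0.75, 0.25, 0.75], [0.75, 0.75, 0.25],
    ])
    idx = np.arange(n_cells)
    cells = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    return (cells[:, None, :] + base[None, :, :]).reshape(-1, 3) * _DIAMOND_A


def _fcc_sites(box: float) -> np.ndarray:
    n_cells = int(np.ceil(box / _FCC_A))
    base = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    idx = np.arange(n_cells)
    cells = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    sites = (cells[:, None, :] + base[None, :, :]).reshape(-1, 3) * _FCC_A
    return sites[(sites < box - 1e-9).all(axis=1)]


def generate_water_like(
    n_molecules: int,
    ldl_fraction: float,
    jitter: float = 0.1,
    seed: int = 0,
) -> Configuration:
    """Oxygen-only configuration with a prescribed LDL-like fraction.

    The box is split into two slabs along x: a tetrahedral diamond-cubic
    slab (LDL-like, Gaussian jitter of amplitude ``jitter``) and a dense
    disordered slab (HDL-like) whose interstitial neighbors at 2.6-3.5 Å
    suppress the LSI below the 0.114 Å² threshold. Molecules near the two
    slab interfaces inherit mixed environments, so per-molecule
    classification is guaranteed only for interior molecules.
    """
    if n_molecules < 8:
        raise InvalidParameterError("need at least 8 molecules")
    if not (0 <= ldl_fraction <= 1):
        raise InvalidParameterError("ldl_fraction must lie in [0, 1]")
    if jitter < 0:
        raise InvalidParameterError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    n_ldl = int(round(ldl_fraction * n_molecules))
    n_hdl = n_molecules - n_ldl
    rho_d = 8.0 / _DIAMOND_A ** 3
    rho_f = 4.0 / _FCC_A ** 3
    # box sized to host both slabs with ~15% margin, commensurate with the
    # diamond lattice so the tetrahedral slab wraps consistently in y, z
    volume = 1.15 * (n_ldl / rho_d + n_hdl / rho_f) + _DIAMOND_A ** 3
    n_cells = max(2, int(np.ceil(volume ** (1.0 / 3.0) / _DIAMOND_A)))
    box = n_cells * _DIAMOND_A

    parts = []
    x_cut = 0.0
    if n_ldl:
        sites = _diamond_sites(n_cells)
        order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
        ldl = sites[order[:n_ldl]]
        ldl = ldl + rng.normal(0.0, jitter, ldl.shape) if jitter else ldl
        parts.append(ldl)
        x_cut = float(np.max(sites[order[:n_ldl], 0])) + 1.5
    if n_hdl:
        sites = _fcc_sites(box)
        sites = sites[sites[:, 0] > x_cut] if n_ldl else sites
        if sites.shape[0] < n_hdl:
            raise PlacementFailureError(
                "dense slab cannot host the requested HDL-like population"
            )
        order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
        hdl = sites[order[:n_hdl]]
        sigma = float(np.hypot(_HDL_DISORDER, jitter))
        hdl = hdl + rng.normal(0.0, sigma, hdl.shape)
        parts.append(hdl)
    pos = np.vstack(parts)
    return Configuration([box] * 3, pos, ["O"] * n_molecules)


def generate_saxs_curve(
    R: float,
    eta: float,
    SA0: float,
    xi: float,
    q_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StructureFactorCurve:
    """SAXS curve S_PY(q; R, η) + S_A(0)/(1 + ξ²q²) + Gaussian noise.

    The noiseless curve is evaluated by the exact model function used by
    the SAXS fitter, so fit round trips are exact at zero noise.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise InvalidParameterError("q_grid must be strictly increasing and positive")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    S = saxs_model(q, R, eta, SA0, xi)
    if noise_sd:
        rng = np.random.default_rng(seed)
        S = S + noise_sd * rng.standard_normal(q.shape)
    stderr = np.full_like(q, noise_sd) if noise_sd else None
    return StructureFactorCurve(q, np.asarray(S), provenance="synthetic", stderr=stderr)


def generate_powerlaw_series(
    amplitude: float,
    exponent: float,
    T_s: float,
    T_grid: Sequence[float],
    noise_rel: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Power-law series value(T) = amplitude ε^(−exponent), ε = (T − T_s)/T_s.

    The amplitude is the prefactor of the power law (the value at ε = 1,
    i.e. T = 2 T_s), not a large-T limit. Relative Gaussian noise is
    multiplicative: value × (1 + noise_rel·N(0,1)).
    """
    T = np.asarray(T_grid, dtype=float)
    _check_positive(amplitude=amplitude, T_s=T_s)
    if np.any(T <= T_s):
        raise InvalidParameterError("all temperatures must exceed T_s")
    if noise_rel < 0:
        raise InvalidParameterError("noise_rel must be non-negative")
    eps = (T - T_s) / T_s
    value = amplitude * eps ** (-exponent)
    if noise_rel:
        rng = np.random.default_rng(seed)
        value = value * (1.0 + noise_rel * rng.standard_normal(T.shape))
    return pd.DataFrame({"T": T, "value": value})


def generate_volume_series(
    mean_V: float,
    kappa_target: float,
    T: float,
    n_samples: int,
    seed: int = 0,
    dt: float = 1.0,
) -> VolumeSeries:
    """I.i.d. Gaussian NPT volume series with a prescribed compressibility.

    The variance is set to κ_T k_B T ⟨V⟩ (in Å⁶; ``kappa_target`` in Pa⁻¹,
    ``mean_V`` in Å³), so the fluctuation estimator recovers
    ``kappa_target`` up to the χ² sampling error of the variance,
    ~ κ√(2/n). ``dt`` is the sample spacing in ps.
    """
    _check_positive(mean_V=mean_V, T=T)
    if kappa_target < 0:
        raise InvalidParameterError("kappa_target must be non-negative")
    if n_samples < 2:
        raise InvalidParameterError("need at least 2 samples")
    # var(V) in Å⁶: κ k_B T ⟨V⟩ with ⟨V⟩ in m³ gives m⁶; × 1e60 → Å⁶
    var = kappa_target * K_B * T * (mean_V * 1e-30) * 1e60
    rng = np.random.default_rng(seed)
    volumes = mean_V + np.sqrt(var) * rng.standard_normal(n_samples)
    times = np.arange(n_samples) * dt
    return VolumeSeries(times, volumes, T)
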