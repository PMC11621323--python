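"""Local structure index (LSI) of water-like configurations.

For each oxygen i, sort the distances to all other oxygens (minimum image)
and count the neighbors n_i inside the O-O cutoff (default 3.7 Å). With the
gap list Δ_j = r_{j+1} − r_j for j = 1…n_i — the last gap spans the cutoff,
i.e. the first neighbor beyond 3.7 Å participates — the index is the
variance of the gaps:

    LSI_i = (1/n_i) Σ_j (Δ_j − ⟨Δ⟩)²   [Å²]

Tetrahedrally ordered (LDL-like) environments show a wide first-to-second
shell gap and hence large LSI; collapsed environments with populated
interstitial shells (HDL-like) show uniformly small gaps and small LSI.
Molecules are classified HDL-like when LSI ≤ 0.114 Å² and LDL-like above.

The module operates on supplied coordinates as-is. Quenched
(inherent-structure) configurations give sharply bimodal LSI
distributions; thermal configurations give broader, less separated ones —
no energy minimization is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from .constants import LSI_CUTOFF, LSI_THRESHOLD
from .datatypes import Configuration, LSIRecord, PopulationFractions
from .errors import InsufficientDataError, InvalidParameterError, NoCrossingError

__all__ = [
    "lsi_per_molecule",
    "lsi_from_distances",
    "classify_populations",
    "population_crossing",
    "LSIResult",
]


def lsi_from_distances(sorted_distances: Sequence[float], cutoff: float = LSI_CUTOFF) -> float:
    """LSI from a pre-sorted ascending neighbor-distance list.

    The list must contain at least one distance beyond the cutoff (the
    first neighbor outside participates in the last gap).
    """
    r = np.asarray(sorted_distances, dtype=float)
    if np.any(np.diff(r) < 0):
        raise InvalidParameterError("distances must be sorted ascending")
    n_i = int(np.sum(r < cutoff))
    if n_i < 1:
        raise InvalidParameterError("no neighbor inside the cutoff")
    if r.size < n_i + 1:
        raise InvalidParameterError("need the first neighbor beyond the cutoff")
    gaps = np.diff(r[: n_i + 1])
    return float(np.mean((gaps - gaps.mean()) ** 2))


@dataclass
class LSIResult:
    """Per-molecule LSI records plus the skipped-molecule report."""

    records: List[LSIRecord]
    skipped_no_neighbors: List[int] = field(default_factory=list)
    skipped_half_box: List[int] = field(default_factory=list)

    def values(self) -> np.ndarray:
        return np.array([rec.lsi_value for rec in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def lsi_per_molecule(
    config: Configuration,
    cutoff: float = LSI_CUTOFF,
    species: str = "O",
) -> LSIResult:
    """LSI for every oxygen in a periodic configuration.

    Neighbor distances use the minimum-image convention via a periodic
    k-d tree; ties are broken by particle index so the sort is
    deterministic. Molecules with no neighbor inside the cutoff, or whose
    first neighbor beyond the cutoff would exceed half the box (where the
    minimum image is ambiguous), are excluded and reported.
    """
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    sub = config.select([species]) if species in config.species else config
    pos = sub.positions
    n = pos.shape[0]
    if n < 3:
        raise InsufficientDataError(f"need ≥ 3 oxygens, got {n}")
    half_box = float(np.min(sub.box)) / 2.0
    if cutoff >= half_box:
        raise InvalidParameterError(
            f"cutoff {cutoff} Å must be below half the box ({half_box} Å)"
        )
    tree = cKDTree(pos, boxsize=sub.box)

    records: List[LSIRecord] = []
    skipped_none: List[int] = []
    skipped_half: List[int] = []
    k = min(n, 24)
    dists, idxs = tree.query(pos, k=k)
    for i in range(n):
        d, j = dists[i, 1:], idxs[i, 1:]
        # grow the neighbor list until one lies beyond the cutoff
        kk = k
        while d.size and d[-1] < cutoff and kk < n:
            kk = min(2 * kk, n)
            d_full, j_full = tree.query(pos[i], k=kk)
            d, j = d_full[1:], j_full[1:]
        order = np.lexsort((j, d))  # deterministic tie-break by index
        d = d[order]
        n_i = int(np.sum(d < cutoff))
        if n_i == 0:
            skipped_none.append(i)
            continue
        if d.size < n_i + 1 or d[n_i] > half_box:
            skipped_half.append(i)
            continue
        shell = d[: n_i + 1]
        gaps = np.diff(shell)
        lsi = float(np.mean((gaps - gaps.mean()) ** 2))
        records.append(LSIRecord(i, lsi, n_i, shell))
    if skipped_half:
        warnings.warn(
            f"{len(skipped_half)} molecules lack a valid neighbor beyond the "
            "cutoff within half the box and were excluded"
        )
    return LSIResult(records, skipped_none, skipped_half)


def classify_populations(
    records,
    threshold: float = LSI_THRESHOLD,
    temperature: Optional[float] = None,
) -> PopulationFractions:
    """HDL-/LDL-like fractions at the given LSI threshold.

    HDL-like: LSI ≤ threshold (boundary values count as HDL-like);
    LDL-like: LSI > threshold.
    """
    if threshold <= 0:
        raise InvalidParameterError("threshold must be positive")
    values = records.values() if hasattr(records, "values") and not isinstance(records, dict) \
        else np.array([rec.lsi_value for rec in records])
    if values.size < 1:
        raise InsufficientDataError("need at least one LSI record")
    hdl = float(np.mean(values <= threshold))
    return PopulationFractions(
        T=temperature if temperature is not None else np.nan,
        fraction_hdl=hdl,
        fraction_ldl=1.0 - hdl,
        threshold=threshold,
        n_molecules=int(values.size),
    )


def population_crossing(
    series: Sequence[PopulationFractions],
    lam: Optional[float] = None,
) -> float:
    """Temperature where the LDL-like fraction crosses 1/2.

    A smoothing spline (generalized cross-validation by default) is fitted
    to fraction_ldl(T); the root of fraction_ldl − 1/2 is returned. If the
    spline crosses several times the root nearest the median temperature is
    returned with a multiplicity warning.
    """
    if len(series) < 4:
        raise InsufficientDataError("need ≥ 4 temperatures")
    T = np.array([p.T for p in series], dtype=float)
    order = np.argsort(T)
    T = T[order]
    f_ldl = np.array([series[i].fraction_ldl for i in order], dtype=float)
    if np.any(np.diff(T) <= 0):
        raise InvalidParameterError("temperatures must be distinct")
    spl = make_smoothing_spline(T, f_ldl, lam=lam)

    def h(t):
        return float(spl(t)) - 0.5

    T_dense = np.linspace(T[0], T[-1], 2001)
    vals = np.array([h(t) for t in T_dense])
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    roots = []
    for i in sign_changes:
        try:
            roots.append(brentq(h, T_dense[i], T_dense[i + 1]))
        except ValueError:
            continue
    exact_zero = T_dense[np.abs(vals) < 1e-15]
    roots.extend(float(t) for t in exact_zero)
    if not roots:
        raise NoCrossingError("fraction_ldl never crosses 1/2 within the data range")
    roots = sorted(set(round(r, 9) for r in roots))
    if len(roots) > 1:
        warnings.warn(f"multiple crossings found ({roots}); returning the one "
                      "nearest the median temperature")
    median_T = float(np.median(T))
    return float(min(roots, key=lambda r: abs(r - median_T)))
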