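"""File readers and writers.

Coordinate files: XYZ (with the box on the comment line, ``box Lx Ly Lz``)
and GRO (via MDAnalysis; nm converted to Å on read). Curves and series:
CSV with a header row. Fit records: JSON.

Public-boundary units: Å, Å⁻¹, K; 0-based particle indexing.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import Configuration, SAXSDecomposition, StructureFactorCurve
from .errors import CurveIOError, InvalidParameterError

__all__ = [
    "read_configuration_file",
    "write_configuration_file",
    "read_curve",
    "write_curve",
    "write_results",
    "read_results",
]

PathLike = Union[str, Path]


def _parse_xyz(path: Path) -> Configuration:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise CurveIOError("XYZ file too short", line_number=len(lines))
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise CurveIOError("first XYZ line must be the atom count", line_number=1)
    comment = lines[1].split()
    box = None
    temperature = None
    for i, tok in enumerate(comment):
        if tok.lower() == "box" and i + 3 < len(comment) + 1:
            try:
                box = [float(v) for v in comment[i + 1:i + 4]]
            except ValueError:
                raise CurveIOError("malformed box entry on the comment line",
                                   line_number=2)
        if tok.startswith("T="):
            try:
                temperature = float(tok[2:])
            except ValueError:
                pass
    if box is None:
        raise CurveIOError(
            "box-required: XYZ comment line must carry 'box Lx Ly Lz'", line_number=2
        )
    if len(lines) < 2 + n:
        raise CurveIOError(f"expected {n} atom lines", line_number=len(lines))
    species, positions = [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise CurveIOError("atom line needs 'species x y z'", line_number=ln)
        species.append(parts[0])
        try:
            positions.append([float(v) for v in parts[1:4]])
        except ValueError:
            raise CurveIOError("malformed coordinate", line_number=ln)
    return Configuration(box, positions, species, temperature)


def _parse_gro(path: Path) -> Configuration:
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    dims = u.dimensions
    if dims is None or np.any(dims[:3] <= 0):
        raise CurveIOError("box-required: GRO file lacks box vectors")
    species = [name.strip("0123456789") or name for name in u.atoms.names]
    return Configuration(dims[:3], u.atoms.positions.astype(float), species)


def read_configuration_file(path: PathLike, format_hint: str = None) -> Configuration:
    """Read an XYZ (box on the comment line) or GRO coordinate file.

    The dialect is chosen by ``format_hint`` ("xyz"/"gro") or the file
    suffix. Positions come back in Å (GRO nm are converted by the reader)
    and wrapped into the primary cell.
    """
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _parse_xyz(path)
    if fmt == "gro":
        return _parse_gro(path)
    raise CurveIOError(f"unrecognized coordinate dialect {fmt!r} (use xyz or gro)")


def write_configuration_file(config: Configuration, path: PathLike) -> Path:
    """Write a configuration to XYZ or GRO, chosen by the file suffix."""
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        lines = [str(config.n_particles)]
        comment = "box {:.8f} {:.8f} {:.8f}".format(*config.box)
        if config.temperature is not None:
            comment += f" T={config.temperature}"
        lines.append(comment)
        for sp, (x, y, z) in zip(config.species, config.positions):
            lines.append(f"{sp} {x:.8f} {y:.8f} {z:.8f}")
        path.write_text("\n".join(lines) + "\n")
        return path
    if fmt == "gro":
        import MDAnalysis as mda
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(config.n_particles, trajectory=True)
            u.add_TopologyAttr("names", list(config.species))
            u.add_TopologyAttr("resnames", ["SOL"])
            u.atoms.positions = config.positions
            u.dimensions = [*config.box, 90.0, 90.0, 90.0]
            u.atoms.write(str(path))
        return path
    raise CurveIOError(f"unrecognized coordinate dialect {fmt!r} (use xyz or gro)")


def read_curve(path: PathLike, temperature: float = None,
               provenance: str = "experiment") -> StructureFactorCurve:
    """Read a structure-factor curve CSV with columns q, S[, stderr]."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CurveIOError("empty curve file")
    for col in ("q", "S"):
        if col not in df.columns:
            raise CurveIOError(f"curve CSV must have a '{col}' column")
    if len(df) == 0:
        raise CurveIOError("empty curve: header only, no data rows")
    q = df["q"].to_numpy(dtype=float)
    if np.any(np.diff(q) <= 0):
        raise CurveIOError("q must be strictly increasing — sort the rows by q")
    stderr = df["stderr"].to_numpy(dtype=float) if "stderr" in df.columns else None
    if temperature is None and "T" in df.columns:
        temperature = float(df["T"].iloc[0])
    return StructureFactorCurve(q, df["S"].to_numpy(dtype=float),
                                temperature=temperature, provenance=provenance,
                                stderr=stderr)


def write_curve(curve: StructureFactorCurve, path: PathLike) -> Path:
    path = Path(path)
    data = {"q": curve.q, "S": curve.S}
    if curve.stderr is not None:
        data["stderr"] = curve.stderr
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, float) and not np.isfinite(value):
        return None
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_results(record, path: PathLike) -> Path:
    """Serialize a result dataclass (or dict) to JSON.

    The record type name is stored under ``"type"`` so the file is
    self-describing and can be validated on read.
    """
    path = Path(path)
    if dataclasses.is_dataclass(record):
        payload = {"type": type(record).__name__,
                   **{k: _jsonable(v) for k, v in dataclasses.asdict(record).items()}}
    elif isinstance(record, dict):
        payload = _jsonable(record)
    else:
        raise InvalidParameterError(f"cannot serialize {type(record).__name__}")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


_SCHEMAS = {
    "SAXSDecomposition": {"R", "eta", "SA0", "xi", "fit_window", "S0_total"},
    "PowerLawFit": {"amplitude", "exponent", "T_s", "R_squared"},
}


def read_results(path: PathLike):
    """Read back a JSON record written by :func:`write_results`.

    Known record types are schema-validated and reconstructed as their
    dataclass; unknown types come back as plain dicts.
    """
    payload = json.loads(Path(path).read_text())
    rtype = payload.get("type")
    required = _SCHEMAS.get(rtype)
    if required and not required.issubset(payload):
        missing = required - set(payload)
        raise CurveIOError(f"{rtype} record missing fields: {sorted(missing)}")
    if rtype == "SAXSDecomposition":
        return SAXSDecomposition(
            R=payload["R"], eta=payload["eta"], SA0=payload["SA0"], xi=payload["xi"],
            fit_window=tuple(payload["fit_window"]), S0_total=payload["S0_total"],
            parameter_stderrs={k: (np.nan if v is None else v)
                               for k, v in payload.get("parameter_stderrs", {}).items()},
            residual_norm=payload.get("residual_norm") or np.nan,
            anomalous_component_absent=payload.get("anomalous_component_absent", False),
        )
    return payload
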