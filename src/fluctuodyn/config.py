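"""Pipeline configuration: a single YAML file with per-stage sections.

Unknown keys are rejected so typos fail loudly; CLI flags override config
values; every CLI run echoes the resolved configuration next to its
outputs for reproducibility.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import InvalidParameterError

__all__ = ["PipelineConfig", "DEFAULTS"]

DEFAULTS = {
    "structure_factor": {
        "bin_width": 0.02,       # Å
        "q1_window": [1.7, 1.9],  # Å⁻¹
        "spline_lam": None,       # smoothing parameter; None → GCV
    },
    "saxs": {
        "window": [0.15, 0.7],    # Å⁻¹
        "fix_R": 1.78,            # Å; null → R free
    },
    "response": {
        "exclusion_margin": 0.02,  # R² improvement flagging a deviation
        "kappa_display_unit": "1e-6/bar",
    },
    "lsi": {
        "threshold": 0.114,  # Å²
        "cutoff": 3.7,       # Å
    },
    "cooling": {
        "alpha": 1.0,        # evaporation coefficient
        "step": 1e-6,        # s
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise InvalidParameterError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


class PipelineConfig:
    """Resolved stage parameters with dotted-key access."""

    def __init__(self, data: Optional[dict] = None):
        self.data = _merge(DEFAULTS, data or {})

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidParameterError("config file must hold a mapping")
        return cls(raw)

    def get(self, dotted: str):
        node = self.data
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise InvalidParameterError(f"unknown config key {dotted!r}")
            node = node[part]
        return node

    def dump(self, path: Union[str, Path]) -> Path:
        """Write the resolved configuration next to the run outputs."""
        path = Path(path)
        path.write_text(yaml.safe_dump(self.data, sort_keys=True))
        return path
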