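"""Run configuration: structured YAML in, stamped artifacts out.

A run configuration names the geometry fixture, grid resolution, boundary
drive (gamma factor, inlet pseudo-shear or mean velocity, hematocrit),
material constants and seeds.  Every artifact a command writes is stamped
with the hash of the configuration that produced it, so paired runs
(RBC vs plasma, gamma vs baseline) can be checked for identical geometry
before ratios are formed.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    fixture: str = "straight"
    fixture_params: dict = field(default_factory=dict)
    target_edge: float = 0.6        # um, wall triangulation
    grid_h: float = 0.6             # um, fluid grid spacing
    mean_inlet_velocity: float = 800.0  # um/s
    gamma: float = 1.0
    hematocrit: float = 0.0
    viscosity_ratio: float = 5.0
    Gs: float | None = None         # pg/s^2; None = package default
    kb: float | None = None
    C: float = 100.0
    t_end: float = 0.02             # s (RBC runs)
    seed: int = 0
    snapshot_every: float = 1e-3    # s
    out_dir: str = "capflow_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def geometry_hash(self) -> str:
        """Hash of the geometry-defining fields only (shared by paired runs)."""
        keys = ("fixture", "fixture_params", "target_edge")
        blob = json.dumps({k: getattr(self, k) for k in keys}, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stamp(self, path) -> None:
        meta = {
            "config": self.to_dict(),
            "config_hash": self.config_hash(),
            "geometry_hash": self.geometry_hash(),
        }
        Path(path).write_text(json.dumps(meta, indent=2))

    def outdir(self) -> Path:
        p = Path(self.out_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p
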