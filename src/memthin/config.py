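"""Run configuration: YAML-backed, validated, lossless round-trip.

A config is a nested mapping whose schema is the DEFAULTS tree below;
unknown keys anywhere are rejected with their full path.  Every random
procedure reads an explicit seed from the config.
"""
from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .geometry import ConfigurationError, ThinningFieldParams, ZoneGeometry
from .species import LipidSpecies, default_species_table

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

DEFAULTS: dict = {
    "geometry": {
        "X_box": 16.0,
        "A_thin": 4.0,
        "A_buffer": 3.0,
        "box_y": 4.5,
        "box_z": 10.0,
    },
    "thinning": {"enabled": True, "k": 20.0, "D": 1.0},
    "composition": {"POPC": 1.0},
    "species": {},  # per-species field overrides, e.g. {POPE: {head_epsilon: 3}}
    "area_per_lipid": 0.255,
    "run": {
        "dt": 0.01,
        "T": 310.0,
        "friction": 1.0,
        "n_steps": 20000,
        "equil_steps": 5000,
        "sample_every": 200,
        "neighbor_skin": 0.3,
        "seed": 0,
    },
    "analysis": {
        "thickness_bins": 110,
        "sorting_bins": 50,
        "defect_grid_spacing": 0.1,
        "defect_A_min": 15.0,
        "defect_p_min": 1.0e-4,
        "defect_n_blocks": 10,
    },
    "umbrella": {
        "x_start": None,  # defaults to thin-zone center at runtime
        "x_end": None,  # defaults to normal-zone center
        "spacing": 0.2,
        "k_u": 1000.0,
        "n_steps": 5000,
        "equil_steps": 1000,
        "sample_every": 10,
        "probe_beads_per_row": 8,
        "probe_epsilon": 2.4,
    },
    "output": {"dir": "memthin_out", "prefix": "run"},
}

_OPEN_MAPS = {"composition", "species"}  # keys whose children are free-form


def _validate(node, defaults, path=""):
    if not isinstance(node, dict):
        raise ConfigurationError(f"config section {path or '<root>'} must be a mapping")
    for key, val in node.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigurationError(f"unknown config key: {here}")
        if key in _OPEN_MAPS:
            if not isinstance(val, dict):
                raise ConfigurationError(f"{here} must be a mapping")
            continue
        if isinstance(defaults[key], dict):
            _validate(val, defaults[key], here)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict) and k not in _OPEN_MAPS:
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


@dataclass
class RunConfig:
    """Validated, fully-merged configuration with typed accessors."""

    data: dict

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "RunConfig":
        mapping = mapping or {}
        _validate(mapping, DEFAULTS)
        return cls(_merge(DEFAULTS, mapping))

    # -- typed views -------------------------------------------------------
    def geometry(self) -> ZoneGeometry:
        g = self.data["geometry"]
        return ZoneGeometry(X_box=g["X_box"], A_thin=g["A_thin"], A_buffer=g["A_buffer"])

    def field(self) -> ThinningFieldParams:
        t = self.data["thinning"]
        return ThinningFieldParams(k=t["k"], D=t["D"], enabled=t["enabled"])

    def species_table(self) -> dict[str, LipidSpecies]:
        table = default_species_table()
        for name, over in self.data["species"].items():
            base = table.get(name, LipidSpecies(name))
            fields = {**base.__dict__, **over, "name": name}
            table[name] = LipidSpecies(**fields)
        return table

    def run_settings(self, seed: int | None = None):
        from .dynamics import RunSettings

        r = self.data["run"]
        return RunSettings(
            dt=r["dt"],
            T=r["T"],
            friction=r["friction"],
            seed=r["seed"] if seed is None else seed,
            neighbor_skin=r["neighbor_skin"],
        )

    def __getitem__(self, key: str):
        return self.data[key]

    # -- persistence -------------------------------------------------------
    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    def content_hash(self) -> str:
        blob = json.dumps(self.data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None loads pure defaults."""
    if path is None:
        return RunConfig.from_mapping({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_mapping(raw)
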