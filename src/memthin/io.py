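"""File formats: GRO coordinates, XYZ dumps, TSV tables, JSON summaries.

GRO files use the fixed-column standard (positions in nm, 3 decimals,
optional velocities); multi-frame trajectories are stored as concatenated
GRO blocks.  Tables are tab-separated with '#'-prefixed header lines so
they stay diff-able and ecosystem-neutral.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .geometry import ZoneGeometry
from .system import MembraneSystem, Trajectory

__all__ = [
    "write_gro",
    "read_gro",
    "write_xyz",
    "write_species_map",
    "read_species_map",
    "write_trajectory_gro",
    "read_trajectory_gro",
    "write_tsv",
    "write_json",
]


def _atom_name(system: MembraneSystem, i: int) -> str:
    if system.lipid_id[i] < 0:
        return "PB" if system.is_tail[i] else "PP"
    return "H1" if system.is_head[i] else "T1"


def _res_name(system: MembraneSystem, i: int) -> str:
    lid = system.lipid_id[i]
    if lid < 0:
        return "PRB"
    return str(system.species_of_lipid[lid])[:5]


def write_gro(
    path: str | Path,
    system: MembraneSystem,
    title: str = "memthin system",
    velocities: bool = True,
    pos: np.ndarray | None = None,
) -> None:
    """Write one GRO frame (fixed columns, nm)."""
    p = system.pos if pos is None else pos
    lines = [title, f"{system.n_beads:5d}"]
    for i in range(system.n_beads):
        resid = (int(system.mol_id[i]) + 1) % 100000
        atom = (i + 1) % 100000
        row = (
            f"{resid:5d}{_res_name(system, i):<5s}{_atom_name(system, i):>5s}"
            f"{atom:5d}{p[i,0]:8.3f}{p[i,1]:8.3f}{p[i,2]:8.3f}"
        )
        if velocities:
            v = system.vel[i]
            row += f"{v[0]:8.4f}{v[1]:8.4f}{v[2]:8.4f}"
        lines.append(row)
    b = system.box
    lines.append(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gro_block(lines: list[str], start: int):
    natoms = int(lines[start + 1])
    pos = np.empty((natoms, 3))
    vel = np.zeros((natoms, 3))
    resids = np.empty(natoms, dtype=np.int64)
    resnames: list[str] = []
    atomnames: list[str] = []
    for k in range(natoms):
        ln = lines[start + 2 + k]
        resids[k] = int(ln[0:5])
        resnames.append(ln[5:10].strip())
        atomnames.append(ln[10:15].strip())
        pos[k] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        if len(ln.rstrip()) >= 68:
            vel[k] = [float(ln[44:52]), float(ln[52:60]), float(ln[60:68])]
    box = np.array([float(v) for v in lines[start + 2 + natoms].split()[:3]])
    return pos, vel, resids, resnames, atomnames, box, start + 3 + natoms


def read_gro(path: str | Path):
    """Read the first frame of a GRO file.

    Returns (pos, vel, resids, resnames, atomnames, box)."""
    lines = Path(path).read_text().splitlines()
    pos, vel, resids, resnames, atomnames, box, _ = _parse_gro_block(lines, 0)
    return pos, vel, resids, resnames, atomnames, box


def write_xyz(
    path: str | Path,
    frames: Iterable[np.ndarray],
    names: Iterable[str],
    comment: str = "",
    append: bool = False,
) -> None:
    """Write frames in plain XYZ (coordinates in nm)."""
    names = list(names)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        for f, p in enumerate(frames):
            fh.write(f"{len(names)}\n{comment} frame {f}\n")
            for nm, (x, y, z) in zip(names, p):
                fh.write(f"{nm} {x:.4f} {y:.4f} {z:.4f}\n")


def write_species_map(path: str | Path, system: MembraneSystem) -> None:
    """Sidecar TSV: lipid_id, species, leaflet (one row per lipid)."""
    head_idx = system.head_index_of_lipid()
    rows = ["# lipid_id\tspecies\tleaflet"]
    for lid in range(system.n_lipids):
        leaf = {1: "upper", -1: "lower", 0: "none"}[
            int(system.leaflet[head_idx[lid]])
        ]
        rows.append(f"{lid}\t{system.species_of_lipid[lid]}\t{leaf}")
    Path(path).write_text("\n".join(rows) + "\n")


def read_species_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment=None,
        names=["lipid_id", "species", "leaflet"],
        skiprows=1,
    )


def write_trajectory_gro(path: str | Path, traj: Trajectory, system: MembraneSystem) -> None:
    """Concatenated multi-frame GRO trajectory."""
    chunks = []
    for f in range(traj.n_frames):
        lines = [f"t= {traj.times[f]:.3f} ps", f"{traj.frames.shape[1]:5d}"]
        p = traj.frames[f]
        for i in range(p.shape[0]):
            resid = (int(system.mol_id[i]) + 1) % 100000
            lines.append(
                f"{resid:5d}{_res_name(system, i):<5s}"
                f"{_atom_name(system, i):>5s}{(i + 1) % 100000:5d}"
                f"{p[i,0]:8.3f}{p[i,1]:8.3f}{p[i,2]:8.3f}"
            )
        b = traj.box
        lines.append(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}")
        chunks.append("\n".join(lines))
    Path(path).write_text("\n".join(chunks) + "\n")


def read_trajectory_gro(
    path: str | Path,
    species_map: pd.DataFrame,
    geom: ZoneGeometry,
    head_radius: float,
    tail_radius: float,
) -> Trajectory:
    """Rebuild a Trajectory from a multi-frame GRO + species sidecar.

    Head/tail roles come from atom names (H*/T* for lipids, PP/PB for the
    probe), leaflets and species from the sidecar.
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    start = 0
    meta = None
    times = []
    while start < len(lines) and lines[start].strip():
        pos, _, resids, resnames, atomnames, box, nxt = _parse_gro_block(
            lines, start
        )
        frames.append(pos)
        title = lines[start]
        times.append(
            float(title.split("=")[1].split()[0]) if "=" in title else len(times)
        )
        if meta is None:
            meta = (resids, resnames, atomnames, box)
        start = nxt
    if meta is None:
        raise ValueError(f"no frames found in {path}")
    resids, resnames, atomnames, box = meta
    is_probe = np.array([rn == "PRB" for rn in resnames])
    is_head = np.array([an.startswith("H") for an in atomnames]) & ~is_probe
    is_tail = np.array([an.startswith("T") for an in atomnames]) & ~is_probe
    lipid_id = np.where(is_probe, -1, resids - 1)
    leaf_of = dict(
        zip(
            species_map["lipid_id"],
            species_map["leaflet"].map({"upper": 1, "lower": -1, "none": 0}),
        )
    )
    leaflet = np.array(
        [0 if lid < 0 else int(leaf_of[lid]) for lid in lipid_id], dtype=np.int8
    )
    species_of_lipid = species_map.sort_values("lipid_id")["species"].to_numpy()
    radii = np.where(is_head | is_probe & ~is_tail, head_radius, tail_radius)
    return Trajectory(
        frames=np.asarray(frames),
        times=np.asarray(times),
        box=box,
        is_head=is_head,
        is_tail=is_tail,
        leaflet=leaflet,
        lipid_id=lipid_id,
        species_of_lipid=species_of_lipid,
        radii=radii,
        geom=geom,
    )


def write_tsv(
    path: str | Path, columns: dict[str, np.ndarray], header_note: str = ""
) -> None:
    """TSV with '#'-prefixed header lines."""
    keys = list(columns)
    n = len(next(iter(columns.values())))
    lines = []
    if header_note:
        lines.append(f"# {header_note}")
    lines.append("# " + "\t".join(keys))
    arrays = [np.asarray(columns[k]) for k in keys]
    for i in range(n):
        lines.append("\t".join(_fmt(a[i]) for a in arrays))
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v) -> str:
    if isinstance(v, (float, np.floating)):
        return f"{v:.12g}"
    return str(v)


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = None
        skip = 0
        for ln in fh:
            if ln.startswith("#"):
                header = ln[1:].strip().split("\t")
                skip += 1
            else:
                break
    return pd.read_csv(path, sep="\t", comment="#", names=header, skiprows=skip)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
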