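"""In-memory containers: bead system, topology and trajectories."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ZoneGeometry

__all__ = ["MembraneSystem", "Trajectory", "BeadState"]

#: Leaflet codes.
UPPER, LOWER, NONE = 1, -1, 0


@dataclass
class BeadState:
    """State of a single coarse-grained particle (convenience view)."""

    r: np.ndarray
    v: np.ndarray
    type_id: int
    lipid_id: int
    is_tail: bool
    leaflet: int

    def __post_init__(self) -> None:
        if self.is_tail and self.lipid_id < 0:
            raise ValueError("tail beads must belong to a lipid")


@dataclass
class MembraneSystem:
    """A bilayer (plus optional probe) with full topology, array-of-structs.

    Positions/velocities are (N, 3) float64 in nm and nm/ps.  ``ptype``
    indexes the per-type tables ``type_sigma`` (WCA diameters) and the
    symmetric pair tables ``pair_eps`` / ``pair_sigma`` used by the
    nonbonded kernel.  Nonbonded interactions are excluded within a
    molecule (equal ``mol_id``).
    """

    pos: np.ndarray
    vel: np.ndarray
    mass: np.ndarray
    box: np.ndarray
    ptype: np.ndarray
    mol_id: np.ndarray
    is_tail: np.ndarray
    is_head: np.ndarray
    leaflet: np.ndarray
    lipid_id: np.ndarray
    species_of_lipid: np.ndarray
    type_sigma: np.ndarray
    pair_eps: np.ndarray
    pair_sigma: np.ndarray
    attraction_width: float
    bonds: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray
    angle_k: np.ndarray
    geom: ZoneGeometry
    composition: dict[str, float] = field(default_factory=dict)
    probe_indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    type_names: list[str] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def n_lipids(self) -> int:
        return len(self.species_of_lipid)

    def bead(self, i: int) -> BeadState:
        return BeadState(
            r=self.pos[i].copy(),
            v=self.vel[i].copy(),
            type_id=int(self.ptype[i]),
            lipid_id=int(self.lipid_id[i]),
            is_tail=bool(self.is_tail[i]),
            leaflet=int(self.leaflet[i]),
        )

    def lipid_mask(self) -> np.ndarray:
        return self.lipid_id >= 0

    def midplane_z(self) -> float:
        """Instantaneous bilayer midplane: mean z of all lipid beads."""
        return float(self.pos[self.lipid_mask(), 2].mean())

    def head_index_of_lipid(self) -> np.ndarray:
        """Index of the (first) head bead of each lipid, ordered by lipid id."""
        mask = self.is_head & (self.lipid_id >= 0)
        idx = np.flatnonzero(mask)
        first = np.full(self.n_lipids, -1, dtype=np.int64)
        for i in idx[::-1]:
            first[self.lipid_id[i]] = i
        return first

    def snapshot(self) -> "MembraneSystem":
        """Deep copy of the mutable state (arrays); topology is shared."""
        import copy

        new = copy.copy(self)
        new.pos = self.pos.copy()
        new.vel = self.vel.copy()
        return new


@dataclass
class Trajectory:
    """A stack of coordinate frames with the static topology needed by analysis.

    ``frames`` has shape (n_frames, N, 3); static per-bead metadata is
    copied from the producing system (or synthesized by a fixture).
    """

    frames: np.ndarray
    times: np.ndarray
    box: np.ndarray
    is_head: np.ndarray
    is_tail: np.ndarray
    leaflet: np.ndarray
    lipid_id: np.ndarray
    species_of_lipid: np.ndarray
    radii: np.ndarray
    geom: ZoneGeometry

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, N, 3)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @classmethod
    def from_system(
        cls, system: MembraneSystem, frames: list[np.ndarray], times: np.ndarray
    ) -> "Trajectory":
        # coverage radius = van der Waals radius (half the potential-minimum
        # distance 2^(1/6) sigma), the convention used by the defect scanner
        radii = 0.5 * 2.0 ** (1.0 / 6.0) * system.type_sigma[system.ptype]
        return cls(
            frames=np.asarray(frames),
            times=np.asarray(times, dtype=np.float64),
            box=system.box.copy(),
            is_head=system.is_head.copy(),
            is_tail=system.is_tail.copy(),
            leaflet=system.leaflet.copy(),
            lipid_id=system.lipid_id.copy(),
            species_of_lipid=system.species_of_lipid.copy(),
            radii=radii,
            geom=system.geom,
        )

    def head_xz(self, frame: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, z, leaflet) of lipid head beads in one frame."""
        m = self.is_head & (self.lipid_id >= 0)
        p = self.frames[frame]
        return p[m, 0], p[m, 2], self.leaflet[m]

    def lipid_head_x(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-lipid head x-coordinate and species label for one frame."""
        m = self.is_head & (self.lipid_id >= 0)
        p = self.frames[frame]
        lid = self.lipid_id[m]
        order = np.argsort(lid, kind="stable")
        x = p[m, 0][order]
        return x, self.species_of_lipid[lid[order]]
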