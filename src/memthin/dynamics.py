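"""Langevin dynamics of a bead system under the internal force field plus
the thinning external field and optional probe restraints.

The integrator is BAOAB splitting: two half-kicks (B) around a pair of
half-drifts (A) with the exact Ornstein-Uhlenbeck velocity update (O) in
the middle.  An implicit-solvent membrane has no momentum-conserving
medium, so a stochastic thermostat is required; BAOAB gives accurate
configurational sampling at coarse-grained time steps.

The thinning field is applied as a bare force (it is not the gradient of
any scalar potential, see :mod:`memthin.geometry`), so it contributes to
neither the reported potential energy nor the virial used for the
pressure tensor.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import (
    _angles,
    _bonds,
    _build_neighbor_list,
    _max_disp2,
    _nonbonded,
    max_pair_cutoff,
    pair_tables,
)
from .geometry import ThinningFieldParams, thinning_force_array
from .system import MembraneSystem, Trajectory
from .units import KB, MN_PER_M_PER_KJ_MOL_NM2

__all__ = [
    "RunSettings",
    "Simulation",
    "ComRestraint",
    "compute_forces",
    "minimize",
    "measure_lateral_tension",
]

MAX_NEIGHBORS = 384


@dataclass(frozen=True)
class RunSettings:
    """Integration settings (MD units: ps, K, ps^-1)."""

    dt: float = 0.01
    T: float = 310.0
    friction: float = 0.3
    seed: int = 0
    neighbor_skin: float = 0.3

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.friction < 0 or self.neighbor_skin <= 0:
            raise ValueError("friction must be >= 0 and skin > 0")


@dataclass
class ComRestraint:
    """Harmonic restraint on the x-COM of a bead group (umbrella bias).

    Potential 0.5 * k * (x_com - center)^2 with mass-weighted COM and
    minimum-image convention in x; each bead receives a share of the
    total restoring force proportional to its mass.
    """

    indices: np.ndarray
    center: float
    k: float

    def com_x(self, pos: np.ndarray, mass: np.ndarray, lx: float) -> float:
        # minimum-image COM relative to the restraint center
        x = pos[self.indices, 0]
        m = mass[self.indices]
        dx = x - self.center
        dx -= lx * np.rint(dx / lx)
        return float(self.center + np.sum(m * dx) / np.sum(m))

    def add_forces(
        self, pos: np.ndarray, mass: np.ndarray, lx: float, forces: np.ndarray
    ) -> float:
        xc = self.com_x(pos, mass, lx)
        total = -self.k * (xc - self.center)
        m = mass[self.indices]
        forces[self.indices, 0] += total * m / m.sum()
        return xc


@dataclass
class ForceReport:
    """Per-call force diagnostics."""

    forces: np.ndarray
    epot: float
    virial: np.ndarray  # diagonal (vxx, vyy, vzz), internal terms only
    field_force_sum: float  # net z-force injected by the thinning field


class NeighborList:
    """Verlet list with displacement-triggered rebuilds."""

    def __init__(self, system: MembraneSystem, skin: float):
        self.skin = skin
        self.cutoff = max_pair_cutoff(
            system.pair_sigma, system.pair_eps, system.attraction_width
        )
        self.rlist = self.cutoff + skin
        self.r_on2, self.rcut2, self.sig2 = pair_tables(
            system.pair_sigma, system.pair_eps, system.attraction_width
        )
        self.ref_pos: np.ndarray | None = None
        self.nbr: np.ndarray | None = None
        self.n_nbr: np.ndarray | None = None

    def update(self, system: MembraneSystem, force: bool = False) -> None:
        if (
            not force
            and self.ref_pos is not None
            and _max_disp2(system.pos, self.ref_pos, system.box)
            < (0.5 * self.skin) ** 2
        ):
            return
        max_nbrs = MAX_NEIGHBORS
        while True:
            nbr, n_nbr, overflow = _build_neighbor_list(
                system.pos, system.box, self.rlist, system.mol_id, max_nbrs
            )
            if not overflow:
                break
            max_nbrs *= 2
        self.nbr, self.n_nbr = nbr, n_nbr
        self.ref_pos = system.pos.copy()


def compute_forces(
    system: MembraneSystem,
    field: ThinningFieldParams | None = None,
    restraints: list[ComRestraint] | None = None,
    nlist: NeighborList | None = None,
) -> ForceReport:
    """Total forces: bonded + nonbonded + thinning field + restraints.

    Newton's third law holds for all internal pair terms; the external
    field and restraints are reported separately in the diagnostics.
    """
    if nlist is None:
        nlist = NeighborList(system, skin=0.4)
    if not np.all(np.isfinite(system.pos)):
        bad = np.flatnonzero(~np.isfinite(system.pos).all(axis=1))
        raise RuntimeError(f"non-finite coordinates on beads {bad[:10].tolist()}")
    nlist.update(system)
    forces = np.zeros_like(system.pos)
    e_nb, vx, vy, vz = _nonbonded(
        system.pos,
        system.box,
        nlist.nbr,
        nlist.n_nbr,
        system.ptype,
        nlist.r_on2,
        nlist.rcut2,
        nlist.sig2,
        system.pair_eps,
        system.attraction_width,
        forces,
    )
    e_b, bx, by, bz = _bonds(
        system.pos, system.box, system.bonds, system.bond_k, system.bond_r0, forces
    )
    e_a, ax, ay, az = _angles(
        system.pos, system.box, system.angles, system.angle_k, forces
    )
    if not np.all(np.isfinite(forces)):
        bad = np.flatnonzero(~np.isfinite(forces).all(axis=1))
        raise RuntimeError(
            f"non-finite forces on beads {bad[:10].tolist()} "
            "(overlapping beads or a blown-up configuration)"
        )
    field_sum = 0.0
    if field is not None and field.enabled and field.k > 0:
        mid = system.midplane_z()
        fz = thinning_force_array(
            system.pos[:, 0],
            system.pos[:, 2] - mid,
            system.geom,
            field,
            system.is_tail,
        )
        forces[:, 2] += fz
        field_sum = float(fz.sum())
    for r in restraints or ():
        r.add_forces(system.pos, system.mass, float(system.box[0]), forces)
    return ForceReport(
        forces=forces,
        epot=e_nb + e_b + e_a,
        virial=np.array([vx + bx + ax, vy + by + ay, vz + bz + az]),
        field_force_sum=field_sum,
    )


def minimize(
    system: MembraneSystem,
    n_steps: int = 200,
    max_disp: float = 0.02,
    f_tol: float = 50.0,
    field: ThinningFieldParams | None = None,
) -> float:
    """Steepest-descent energy relaxation with capped displacements.

    Moves every bead along the force, the largest move capped at
    ``max_disp`` nm per iteration; stops early once the largest force
    drops below ``f_tol`` kJ mol^-1 nm^-1.  Returns the final potential
    energy.  Standard post-build step to relax lattice contacts before
    dynamics.
    """
    nlist = NeighborList(system, skin=0.4)
    report = compute_forces(system, field, None, nlist)
    for _ in range(n_steps):
        fmax = float(np.abs(report.forces).max())
        if fmax < f_tol:
            break
        system.pos += report.forces * (max_disp / fmax)
        system.pos %= system.box
        report = compute_forces(system, field, None, nlist)
    return float(report.epot)


@dataclass
class FrameLog:
    """Scalar time series sampled during a run."""

    step: list[int] = field(default_factory=list)
    time: list[float] = field(default_factory=list)
    kinetic: list[float] = field(default_factory=list)
    potential: list[float] = field(default_factory=list)
    T_inst: list[float] = field(default_factory=list)
    tension: list[float] = field(default_factory=list)
    com_x: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v) for k, v in self.__dict__.items()}


class Simulation:
    """Owns the mutable state of one Langevin run.

    Deterministic for fixed (system, settings.seed): the only stochastic
    element is the thermostat noise from a PCG64 generator.
    """

    def __init__(
        self,
        system: MembraneSystem,
        settings: RunSettings,
        field: ThinningFieldParams | None = None,
        restraints: list[ComRestraint] | None = None,
    ):
        self.system = system
        self.settings = settings
        self.field = field
        self.restraints = list(restraints or [])
        self.rng = np.random.default_rng(settings.seed)
        self.nlist = NeighborList(system, settings.neighbor_skin)
        self.step_count = 0
        self._ou_c1 = float(np.exp(-settings.friction * settings.dt))
        self._ou_c2 = np.sqrt(
            (1.0 - self._ou_c1**2) * KB * settings.T / system.mass
        )[:, None]
        self.report = compute_forces(system, field, self.restraints, self.nlist)

    # -- integration -------------------------------------------------------
    def step(self, n: int = 1) -> None:
        """Advance ``n`` BAOAB steps."""
        s, st = self.system, self.settings
        dt = st.dt
        inv_m = (1.0 / s.mass)[:, None]
        max_move = max(0.5 * self.nlist.cutoff, 0.2)
        for _ in range(n):
            s.vel += 0.5 * dt * self.report.forces * inv_m
            old = s.pos.copy()
            s.pos += 0.5 * dt * s.vel
            s.vel *= self._ou_c1
            s.vel += self._ou_c2 * self.rng.standard_normal(s.vel.shape)
            s.pos += 0.5 * dt * s.vel
            disp = np.abs(s.pos - old)
            # displacement check before wrapping: wrap jumps are not physical moves
            if disp.max() > max_move:
                i = int(np.argmax(disp.max(axis=1)))
                raise RuntimeError(
                    f"blow-up: bead {i} moved {disp.max():.3f} nm in one step "
                    f"(> {max_move:.3f})"
                )
            s.pos %= s.box  # periodic wrap in x, y, z
            self.report = compute_forces(s, self.field, self.restraints, self.nlist)
            s.vel += 0.5 * dt * self.report.forces * inv_m  # closing B kick
            self.step_count += 1

    # -- diagnostics -------------------------------------------------------
    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.system.mass[:, None] * self.system.vel**2))

    def instantaneous_T(self) -> float:
        ndof = 3 * self.system.n_beads
        return 2.0 * self.kinetic_energy() / (ndof * KB)

    def pressure_diag(self) -> np.ndarray:
        """Diagonal of the virial pressure tensor (kJ mol^-1 nm^-3)."""
        s = self.system
        vol = float(np.prod(s.box))
        kin = np.sum(s.mass[:, None] * s.vel**2, axis=0)
        return (kin + self.report.virial) / vol

    def instantaneous_tension(self) -> float:
        """gamma = Lz * (Pzz - (Pxx + Pyy)/2) in kJ mol^-1 nm^-2."""
        p = self.pressure_diag()
        return float(self.system.box[2] * (p[2] - 0.5 * (p[0] + p[1])))

    # -- production --------------------------------------------------------
    def run(
        self,
        n_steps: int,
        sample_every: int = 200,
        collect_frames: bool = True,
    ) -> tuple[Trajectory | None, FrameLog]:
        """Run ``n_steps``, sampling scalars (and optionally frames)."""
        frames: list[np.ndarray] = []
        log = FrameLog()
        lx = float(self.system.box[0])
        for start in range(0, n_steps, sample_every):
            self.step(min(sample_every, n_steps - start))
            log.step.append(self.step_count)
            log.time.append(self.step_count * self.settings.dt)
            log.kinetic.append(self.kinetic_energy())
            log.potential.append(self.report.epot)
            log.T_inst.append(self.instantaneous_T())
            log.tension.append(self.instantaneous_tension())
            if self.restraints:
                log.com_x.append(
                    self.restraints[0].com_x(
                        self.system.pos, self.system.mass, lx
                    )
                )
            if collect_frames:
                frames.append(self.system.pos.copy())
        traj = None
        if collect_frames:
            traj = Trajectory.from_system(
                self.system, frames, np.asarray(log.time)
            )
        return traj, log


def measure_lateral_tension(
    tension_series: np.ndarray, n_blocks: int = 10
) -> tuple[float, float]:
    """Block-averaged lateral tension in mN/m from a sampled series.

    Splits the (equilibrated) series into ``n_blocks`` consecutive blocks
    and returns (mean, standard error).  Raises if the window is shorter
    than ``n_blocks`` samples.
    """
    g = np.asarray(tension_series, dtype=float)
    if g.size < n_blocks:
        raise ValueError(
            f"tension window has {g.size} samples; need >= {n_blocks} blocks"
        )
    blocks = np.array_split(g, n_blocks)
    means = np.array([b.mean() for b in blocks]) * MN_PER_M_PER_KJ_MOL_NM2
    return float(means.mean()), float(means.std(ddof=1) / np.sqrt(n_blocks))
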