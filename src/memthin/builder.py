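"""Seeded construction of bilayer systems and the amphipathic probe.

``build_bilayer`` places lipids on two opposing leaflet lattices at a
requested area per lipid, assigns species by a seeded permutation that
matches the requested mole fractions to within one lipid per leaflet, and
wires up the full bonded topology.  ``build_probe`` constructs a rigid
two-row amphipathic bead probe (hydrophobic row + polar row) that serves
as a generic stand-in for defect-sensing amphipathic helices such as the
ALPS motif.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationError, ZoneGeometry
from .species import DEFAULT_AREA_PER_LIPID, LipidSpecies, default_species_table
from .system import LOWER, NONE, UPPER, MembraneSystem
from .units import KB

__all__ = ["build_bilayer", "build_probe", "attach_probe", "AmphipathicProbe"]

#: WCA diameters (nm).
SIGMA_TAIL = 0.5
SIGMA_HEAD = 0.475
#: Range of the cos^2 attraction beyond the WCA minimum (nm).
ATTRACTION_WIDTH = 0.8
#: Bead mass (amu); a free coarse-graining choice that sets the time scale.
BEAD_MASS = 18.0
#: Harmonic bond constant (kJ mol^-1 nm^-2) for lipid chains.
BOND_K = 800.0
#: Minimum number of lipids per leaflet for a meaningful zone analysis.
MIN_LIPIDS_PER_LEAFLET = 100

MIN_BUILD_SEPARATION = 0.3  # nm, build-time contact limit


def _species_counts(n: int, composition: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` lipids to mole fractions."""
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"mole fractions sum to {total}, expected 1")
    names = sorted(composition)
    raw = {s: composition[s] * n for s in names}
    counts = {s: int(np.floor(raw[s])) for s in names}
    short = n - sum(counts.values())
    for s in sorted(names, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    return counts


def _build_type_tables(
    species: list[LipidSpecies], probe_epsilon: float | None = None
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray, dict[str, tuple[int, int]]]:
    """Per-species head/tail bead types and symmetric pair tables.

    Attraction couples tail beads with tail beads (sqrt mixing of
    ``tail_epsilon``) and head beads with head beads (sqrt mixing of
    ``head_epsilon``); head-tail pairs are purely repulsive.  If
    ``probe_epsilon`` is given, two extra types are appended: a
    hydrophobic probe bead that attracts lipid tails and a polar probe
    bead that is purely repulsive.
    """
    names: list[str] = []
    sigma: list[float] = []
    head_eps: list[float] = []
    tail_eps: list[float] = []
    kind: list[str] = []  # 'head' | 'tail'
    type_of: dict[str, tuple[int, int]] = {}
    for sp in species:
        type_of[sp.name] = (len(names), len(names) + 1)
        names += [f"{sp.name}_H", f"{sp.name}_T"]
        sigma += [sp.head_sigma, SIGMA_TAIL]
        head_eps += [sp.head_epsilon, 0.0]
        tail_eps += [0.0, sp.tail_epsilon]
        kind += ["head", "tail"]
    if probe_epsilon is not None:
        names += ["PRB_PHOB", "PRB_POL"]
        sigma += [SIGMA_TAIL, SIGMA_HEAD]
        head_eps += [0.0, 0.0]
        tail_eps += [probe_epsilon, 0.0]
        kind += ["tail", "head"]

    t = len(names)
    sig = np.asarray(sigma)
    pair_sigma = 0.5 * (sig[:, None] + sig[None, :])
    he = np.asarray(head_eps)
    te = np.asarray(tail_eps)
    pair_eps = np.sqrt(np.outer(he, he)) + np.sqrt(np.outer(te, te))
    return names, sig, pair_sigma, pair_eps, type_of


def build_bilayer(
    geom: ZoneGeometry,
    composition: dict[str, float],
    area_per_lipid: float = DEFAULT_AREA_PER_LIPID,
    seed: int = 0,
    box_y: float = 10.0,
    box_z: float = 10.0,
    species_table: dict[str, LipidSpecies] | None = None,
    T_init: float = 310.0,
    probe_epsilon: float = 2.4,
) -> MembraneSystem:
    """Construct a flat mixed bilayer on two leaflet lattices.

    The number of lipids per leaflet is ``floor(X_box * box_y /
    area_per_lipid)``; species are assigned by a seeded random
    permutation so that per-leaflet counts match the requested fractions
    to within one lipid.  Initial velocities are Maxwell-Boltzmann at
    ``T_init``.  Deterministic for a fixed seed.
    """
    if area_per_lipid <= 0:
        raise ConfigurationError("area_per_lipid must be > 0")
    table = dict(species_table or default_species_table())
    for name in composition:
        if name not in table:
            raise ConfigurationError(f"unknown lipid species {name!r}")
    rng = np.random.default_rng(seed)

    lx, ly = geom.X_box, box_y
    n_per_leaflet = int(np.floor(lx * ly / area_per_lipid))
    if n_per_leaflet < MIN_LIPIDS_PER_LEAFLET:
        raise ConfigurationError(
            f"box supports only {n_per_leaflet} lipids/leaflet "
            f"(< {MIN_LIPIDS_PER_LEAFLET}); enlarge the box or reduce "
            "area_per_lipid"
        )
    counts = _species_counts(n_per_leaflet, composition)
    species_used = [table[s] for s in sorted(composition)]
    type_names, type_sigma, pair_sigma, pair_eps, type_of = _build_type_tables(
        species_used, probe_epsilon=probe_epsilon
    )

    # leaflet lattice: near-square grid with >= n sites; drop random extras
    nx = max(1, int(round(np.sqrt(n_per_leaflet * lx / ly))))
    ny = int(np.ceil(n_per_leaflet / nx))
    sx, sy = lx / nx, ly / ny

    # species labels per leaflet site, seeded permutation
    def leaflet_labels() -> np.ndarray:
        labels = np.concatenate(
            [np.repeat(s, c) for s, c in sorted(counts.items())]
        )
        return rng.permutation(labels)

    # chain z-stacking: terminal tail bead near the midplane, head on top
    dz = SIGMA_TAIL  # bond rest length along the chain
    z_mid = box_z / 2.0

    pos, ptype, mol_id, lipid_id = [], [], [], []
    is_tail, is_head, leaflet_arr = [], [], []
    bonds, bond_k, bond_r0 = [], [], []
    angles, angle_k = [], []
    species_of_lipid: list[str] = []

    lipid_counter = 0
    for side, zsign in ((UPPER, 1.0), (LOWER, -1.0)):
        labels = leaflet_labels()
        sites = rng.permutation(nx * ny)[:n_per_leaflet]
        offset = 0.0 if side == UPPER else 0.5  # stagger leaflets in xy
        for site, label in zip(sites, labels):
            sp = table[label]
            ix, iy = divmod(int(site), ny)
            x0 = (ix + 0.25 + offset) % nx * sx
            y0 = (iy + 0.25 + offset) % ny * sy
            base = len(pos)
            th, tt = type_of[label]
            n_t = sp.n_tail_beads
            half_gap = 0.25 * np.sqrt(area_per_lipid)  # scale with lattice
            chain_off = [0.0] if sp.n_chains == 1 else [-half_gap, half_gap]
            # head bead sits above the first tail bead of the first chain
            z_top = z_mid + zsign * (0.35 + n_t * dz)
            pos.append([x0, y0, z_top])
            ptype.append(th)
            is_tail.append(False)
            is_head.append(True)
            head_index = base
            for ci, xoff in enumerate(chain_off):
                prev = head_index
                for b in range(n_t):
                    z = z_mid + zsign * (0.35 + (n_t - 1 - b) * dz)
                    pos.append([x0 + xoff, y0, z])
                    ptype.append(tt)
                    is_tail.append(True)
                    is_head.append(False)
                    idx = base + 1 + ci * n_t + b
                    r0 = (
                        0.5 * (sp.head_sigma + SIGMA_TAIL)
                        if prev == head_index
                        else SIGMA_TAIL
                    )
                    bonds.append([prev, idx])
                    bond_k.append(BOND_K)
                    bond_r0.append(r0)
                    prev = idx
                # straightening: all consecutive triplets along the chain
                chain = [head_index] + [
                    base + 1 + ci * n_t + b for b in range(n_t)
                ]
                for a in range(len(chain) - 2):
                    angles.append(chain[a : a + 3])
                    angle_k.append(sp.bend_k)
            if sp.n_chains == 2:
                # glycerol-backbone surrogate: rungs tie sister beads so the
                # two chains move as one double-width tail
                for b in range(n_t):
                    i1 = base + 1 + b
                    i2 = base + 1 + n_t + b
                    bonds.append([i1, i2])
                    bond_k.append(BOND_K)
                    bond_r0.append(2 * half_gap)
            n_beads_lipid = 1 + sp.n_chains * n_t
            mol_id += [lipid_counter] * n_beads_lipid
            lipid_id += [lipid_counter] * n_beads_lipid
            leaflet_arr += [side] * n_beads_lipid
            species_of_lipid.append(label)
            lipid_counter += 1

    pos_arr = np.asarray(pos, dtype=np.float64)
    pos_arr[:, 0] %= lx
    pos_arr[:, 1] %= ly
    n = pos_arr.shape[0]
    mass = np.full(n, BEAD_MASS)
    vel = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(KB * T_init / BEAD_MASS)
    vel -= vel.mean(axis=0)  # no net drift

    system = MembraneSystem(
        pos=pos_arr,
        vel=vel,
        mass=mass,
        box=np.array([lx, ly, box_z]),
        ptype=np.asarray(ptype, dtype=np.int64),
        mol_id=np.asarray(mol_id, dtype=np.int64),
        is_tail=np.asarray(is_tail, dtype=bool),
        is_head=np.asarray(is_head, dtype=bool),
        leaflet=np.asarray(leaflet_arr, dtype=np.int8),
        lipid_id=np.asarray(lipid_id, dtype=np.int64),
        species_of_lipid=np.asarray(species_of_lipid),
        type_sigma=type_sigma,
        pair_eps=pair_eps,
        pair_sigma=pair_sigma,
        attraction_width=ATTRACTION_WIDTH,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        bond_k=np.asarray(bond_k),
        bond_r0=np.asarray(bond_r0),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        angle_k=np.asarray(angle_k),
        geom=geom,
        composition=dict(composition),
        type_names=type_names,
    )
    _check_min_separation(system)
    return system


def _check_min_separation(system: MembraneSystem) -> None:
    """Build-time sanity check: no inter-molecular pair closer than 0.3 nm."""
    from .forcefield import _build_neighbor_list

    nbr, n_nbr, _ = _build_neighbor_list(
        system.pos, system.box, MIN_BUILD_SEPARATION, system.mol_id, 64
    )
    if n_nbr.sum() > 0:
        raise ConfigurationError(
            "built configuration has inter-molecular contacts closer than "
            f"{MIN_BUILD_SEPARATION} nm"
        )


@dataclass
class AmphipathicProbe:
    """Rigid two-row amphipathic bead probe (defect-sensing surrogate).

    Row 0 is hydrophobic (tail-attracting), row 1 polar (repulsive); the
    rows run along y and are held rigid by a stiff harmonic bond network
    (in-row, rung, diagonal and next-nearest bonds).
    """

    pos: np.ndarray
    hydrophobic: np.ndarray
    bonds: np.ndarray
    bond_r0: np.ndarray
    bond_k: float
    spacing: float
    row_gap: float

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    def com_x(self) -> float:
        return float(self.pos[:, 0].mean())


def build_probe(
    n_beads_per_row: int,
    seed: int = 0,
    geom: ZoneGeometry | None = None,
    y_center: float = 5.0,
    surface_z: float = 5.0,
    spacing: float = 0.5,
    row_gap: float = 0.55,
    bond_stiffness: float = 4000.0,
) -> AmphipathicProbe:
    """Build the rigid amphipathic probe at the thin-zone center.

    The hydrophobic row sits at ``surface_z`` (facing the bilayer
    interior when attached above the upper leaflet), the polar row
    directly above it on the solvent side.
    """
    if n_beads_per_row < 3:
        raise ConfigurationError("n_beads_per_row must be >= 3")
    x_c = geom.x_c if geom is not None else 0.0
    n = n_beads_per_row
    y = (np.arange(n) - (n - 1) / 2.0) * spacing + y_center
    pos = np.zeros((2 * n, 3))
    pos[:n] = np.column_stack([np.full(n, x_c), y, np.full(n, surface_z)])
    pos[n:] = np.column_stack(
        [np.full(n, x_c), y, np.full(n, surface_z + row_gap)]
    )
    hydrophobic = np.zeros(2 * n, dtype=bool)
    hydrophobic[:n] = True

    bonds: list[list[int]] = []
    r0: list[float] = []
    diag = float(np.hypot(spacing, row_gap))
    for r in (0, 1):
        off = r * n
        for i in range(n - 1):
            bonds.append([off + i, off + i + 1])
            r0.append(spacing)
        for i in range(n - 2):  # next-nearest: in-row bending stiffness
            bonds.append([off + i, off + i + 2])
            r0.append(2 * spacing)
    for i in range(n):  # rungs
        bonds.append([i, n + i])
        r0.append(row_gap)
    for i in range(n - 1):  # shear-blocking diagonals
        bonds.append([i, n + i + 1])
        r0.append(diag)
        bonds.append([i + 1, n + i])
        r0.append(diag)

    return AmphipathicProbe(
        pos=pos,
        hydrophobic=hydrophobic,
        bonds=np.asarray(bonds, dtype=np.int64),
        bond_r0=np.asarray(r0),
        bond_k=bond_stiffness,
        spacing=spacing,
        row_gap=row_gap,
    )


def attach_probe(
    system: MembraneSystem,
    probe: AmphipathicProbe,
    clearance: float = 0.15,
    T_init: float = 310.0,
    seed: int = 0,
) -> MembraneSystem:
    """Return a new system with the probe appended above the upper leaflet.

    The hydrophobic row is placed ``clearance`` nm above the highest
    upper-leaflet head bead at the probe's x position; probe bead types
    must already exist in the system's type tables (they do for systems
    made by :func:`build_bilayer`).
    """
    names = system.type_names
    if "PRB_PHOB" not in names:
        raise ConfigurationError("system was built without probe types")
    t_phob = names.index("PRB_PHOB")
    t_pol = names.index("PRB_POL")
    rng = np.random.default_rng(seed)

    heads = system.is_head & (system.lipid_id >= 0) & (system.leaflet == UPPER)
    top = float(system.pos[heads, 2].max())
    ppos = probe.pos.copy()
    ppos[:, 2] += (top + clearance) - ppos[probe.hydrophobic, 2].min()

    n_old = system.n_beads
    n_p = probe.n_beads
    pos = np.vstack([system.pos, ppos])
    mass = np.concatenate([system.mass, np.full(n_p, BEAD_MASS)])
    vel = np.vstack(
        [
            system.vel,
            rng.normal(0.0, 1.0, (n_p, 3)) * np.sqrt(KB * T_init / BEAD_MASS),
        ]
    )
    ptype = np.concatenate(
        [system.ptype, np.where(probe.hydrophobic, t_phob, t_pol)]
    )
    mol = np.concatenate(
        [system.mol_id, np.full(n_p, system.mol_id.max() + 1)]
    )
    out = MembraneSystem(
        pos=pos,
        vel=vel,
        mass=mass,
        box=system.box.copy(),
        ptype=ptype,
        mol_id=mol,
        is_tail=np.concatenate([system.is_tail, np.zeros(n_p, bool)]),
        is_head=np.concatenate([system.is_head, np.zeros(n_p, bool)]),
        leaflet=np.concatenate([system.leaflet, np.full(n_p, NONE, np.int8)]),
        lipid_id=np.concatenate([system.lipid_id, np.full(n_p, -1)]),
        species_of_lipid=system.species_of_lipid.copy(),
        type_sigma=system.type_sigma,
        pair_eps=system.pair_eps,
        pair_sigma=system.pair_sigma,
        attraction_width=system.attraction_width,
        bonds=np.vstack([system.bonds, probe.bonds + n_old]),
        bond_k=np.concatenate(
            [system.bond_k, np.full(probe.bonds.shape[0], probe.bond_k)]
        ),
        bond_r0=np.concatenate([system.bond_r0, probe.bond_r0]),
        angles=system.angles,
        angle_k=system.angle_k,
        geom=system.geom,
        composition=dict(system.composition),
        probe_indices=np.arange(n_old, n_old + n_p),
        type_names=list(names),
    )
    return out
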