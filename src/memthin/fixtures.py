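"""Seeded synthetic fixtures with embedded ground truth.

Every analysis operation in the package can be tested as parameter
recovery on data generated here: membranes with a known thickness
profile, leaflets with hand-countable packing defects, lipid mixtures
with known composition, and umbrella windows sampled exactly from a
known free-energy landscape.  Each generator returns ``(object, truth)``
where ``truth`` is a JSON-serializable dict of the generating
parameters; :func:`make_fixture` dispatches by kind and can write the
files plus a truth sidecar.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .free_energy import UmbrellaWindow
from .geometry import ZoneGeometry
from .system import Trajectory
from .thickness import sigmoid
from .units import KB

__all__ = ["make_fixture", "FIXTURE_KINDS"]

#: Reference sigmoid parameter set for the thinned-membrane thickness
#: profile (amplitude nm, steepness 1/nm, midpoint nm, baseline nm).
REFERENCE_SIGMOID = {"L": -1.22, "kappa": -19.14, "x0": 1.11, "b": 4.08}

HEAD_RADIUS = 0.3
TAIL_RADIUS = 0.25


def _head_only_trajectory(
    frames: np.ndarray,
    box: np.ndarray,
    leaflet: np.ndarray,
    geom: ZoneGeometry,
    species: np.ndarray | None = None,
    radii: np.ndarray | None = None,
    is_tail: np.ndarray | None = None,
) -> Trajectory:
    n = frames.shape[1]
    if species is None:
        species = np.repeat("POPC", n)
    if is_tail is None:
        is_tail = np.zeros(n, dtype=bool)
    if radii is None:
        radii = np.where(is_tail, TAIL_RADIUS, HEAD_RADIUS)
    return Trajectory(
        frames=frames,
        times=np.arange(frames.shape[0], dtype=float),
        box=box,
        is_head=~is_tail,
        is_tail=is_tail,
        leaflet=leaflet,
        lipid_id=np.arange(n),
        species_of_lipid=species,
        radii=radii,
        geom=geom,
    )


def flat_membrane(
    thickness: float = 4.0,
    geom: ZoneGeometry | None = None,
    box_y: float = 10.0,
    apl: float = 0.65,
    noise: float = 0.0,
    n_frames: int = 5,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Two flat leaflet surfaces of head beads at z = +-thickness/2."""
    if geom is None:
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
    rng = np.random.default_rng(seed)
    n = int(geom.X_box * box_y / apl)
    z0 = 5.0
    z_sign = np.concatenate([np.ones(n), -np.ones(n)])
    leaflet = z_sign.astype(np.int8)
    frames = np.empty((n_frames, 2 * n, 3))
    for f in range(n_frames):
        x = rng.uniform(0, geom.X_box, 2 * n)
        y = rng.uniform(0, box_y, 2 * n)
        z = z0 + z_sign * thickness / 2.0
        if noise > 0:
            z = z + rng.normal(0.0, noise, 2 * n)
        frames[f] = np.column_stack([x, y, z])
    box = np.array([geom.X_box, box_y, 2 * z0])
    traj = _head_only_trajectory(frames, box, leaflet, geom)
    return traj, {"kind": "flat_membrane", "thickness": thickness, "noise": noise}


def sigmoid_membrane(
    geom: ZoneGeometry | None = None,
    params: dict | None = None,
    box_y: float = 10.0,
    apl: float = 0.65,
    noise: float = 0.0,
    n_frames: int = 5,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Head beads tracing the thinned-membrane thickness profile.

    The local thickness a(x) follows the reference sigmoid in the
    coordinate "outward distance from the thin-zone edge", mirrored on
    both sides of the thin-zone center, so the thin zone sits at the
    lower asymptote b + L and the normal zone at b.
    """
    if geom is None:
        geom = ZoneGeometry(X_box=55.0, A_thin=10.0, A_buffer=10.0)
    p = dict(REFERENCE_SIGMOID)
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    n = int(geom.X_box * box_y / apl)
    z0 = 5.0
    frames = np.empty((n_frames, 2 * n, 3))
    z_sign = np.concatenate([np.ones(n), -np.ones(n)])
    leaflet = z_sign.astype(np.int8)
    for f in range(n_frames):
        x = rng.uniform(0, geom.X_box, 2 * n)
        y = rng.uniform(0, box_y, 2 * n)
        xi = np.abs(x - geom.x_c) - geom.thin_half
        a = sigmoid(xi, p["L"], p["kappa"], p["x0"], p["b"])
        z = z0 + z_sign * a / 2.0
        if noise > 0:
            z = z + rng.normal(0.0, noise, 2 * n)
        frames[f] = np.column_stack([x, y, z])
    box = np.array([geom.X_box, box_y, 2 * z0])
    traj = _head_only_trajectory(frames, box, leaflet, geom)
    return traj, {"kind": "sigmoid_membrane", **p, "noise": noise}


def defect_lattice(
    zone_x: tuple[float, float] = (0.0, 8.0),
    box_y: float = 8.0,
    spacing: float = 0.5,
    holes: list[tuple[int, int]] | int = 1,
    grid_spacing: float = 0.1,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """A dense head lattice with lipid-tail beads exposed in hole sites.

    Heads sit on a square lattice that covers the surface; at each hole
    site the head is removed, exposing the tail bead underneath.  The
    true per-hole defect area (in grid cells of ``grid_spacing``) is
    computed by brute-force cell coverage and stored in the truth dict.
    """
    rng = np.random.default_rng(seed)
    x_lo, x_hi = zone_x
    nx = int(round((x_hi - x_lo) / spacing))
    ny = int(round(box_y / spacing))
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    hx = x_lo + (gx.ravel() + 0.5) * spacing
    hy = (gy.ravel() + 0.5) * spacing
    if isinstance(holes, int):
        sites = rng.choice(nx * ny, size=holes, replace=False)
        holes = [(int(s) // ny, int(s) % ny) for s in sites]
    hole_idx = {h[0] * ny + h[1] for h in holes}
    keep = np.array([i not in hole_idx for i in range(nx * ny)])

    head_pos = np.column_stack([hx[keep], hy[keep], np.full(keep.sum(), 7.0)])
    # tail layer below the heads, dense enough to cover every cell
    tail_pos = np.column_stack([hx, hy, np.full(nx * ny, 6.4)])
    pos = np.vstack([head_pos, tail_pos])
    n_heads, n_tails = head_pos.shape[0], tail_pos.shape[0]
    is_tail = np.concatenate([np.zeros(n_heads, bool), np.ones(n_tails, bool)])
    leaflet = np.ones(n_heads + n_tails, dtype=np.int8)
    box = np.array([x_hi + spacing, box_y, 10.0])
    geom = ZoneGeometry(X_box=box[0], A_thin=(x_hi - x_lo) / 2, A_buffer=spacing)
    traj = Trajectory(
        frames=pos[None, :, :],
        times=np.zeros(1),
        box=box,
        is_head=~is_tail,
        is_tail=is_tail,
        leaflet=leaflet,
        lipid_id=np.arange(n_heads + n_tails),
        species_of_lipid=np.repeat("POPC", n_heads + n_tails),
        radii=np.where(is_tail, TAIL_RADIUS, HEAD_RADIUS),
        geom=geom,
    )
    true_areas = _uncovered_areas(
        head_pos, HEAD_RADIUS, zone_x, box_y, grid_spacing
    )
    return traj, {
        "kind": "defect_lattice",
        "holes": [list(h) for h in holes],
        "true_areas_A2": true_areas,
        "grid_spacing": grid_spacing,
    }


def _uncovered_areas(
    head_pos: np.ndarray,
    radius: float,
    zone_x: tuple[float, float],
    box_y: float,
    grid_spacing: float,
) -> list[float]:
    """Brute-force oracle: cluster grid cells not covered by any head disk."""
    from scipy import ndimage

    x_lo, x_hi = zone_x
    nx = int(round((x_hi - x_lo) / grid_spacing))
    ny = int(round(box_y / grid_spacing))
    cx = x_lo + (np.arange(nx) + 0.5) * grid_spacing
    cy = (np.arange(ny) + 0.5) * grid_spacing
    covered = np.zeros((nx, ny), dtype=bool)
    for px, py, _ in head_pos:
        dx = cx - px
        dy = cy - py
        dy = dy - box_y * np.rint(dy / box_y)
        covered |= (dx[:, None] ** 2 + dy[None, :] ** 2) <= radius**2
    labels, n = ndimage.label(~covered)
    areas = []
    for k in range(1, n + 1):
        areas.append(float((labels == k).sum() * (grid_spacing * 10.0) ** 2))
    return areas


def sorted_mix(
    geom: ZoneGeometry | None = None,
    box_y: float = 10.0,
    n_lipids: int = 1000,
    minority_fraction: float = 0.3,
    mode: str = "uniform",
    n_frames: int = 20,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Two-species head-bead mixture with known spatial sorting.

    Modes: 'uniform' (no sorting; every bin should read the global
    fraction) and 'minority_in_thin' (all minority lipids confined to the
    thin zone; normal-zone content is exactly zero).
    """
    if geom is None:
        geom = ZoneGeometry(X_box=50.0, A_thin=10.0, A_buffer=10.0)
    rng = np.random.default_rng(seed)
    n_min = int(round(n_lipids * minority_fraction))
    species = np.array(["MINOR"] * n_min + ["POPC"] * (n_lipids - n_min))
    leaflet = np.where(np.arange(n_lipids) % 2 == 0, 1, -1).astype(np.int8)
    frames = np.empty((n_frames, n_lipids, 3))
    t0, t1 = geom.thin_range()
    for f in range(n_frames):
        x = rng.uniform(0, geom.X_box, n_lipids)
        if mode == "minority_in_thin":
            x[:n_min] = rng.uniform(t0, t1, n_min)
        elif mode != "uniform":
            raise ValueError(f"unknown mode {mode!r}")
        y = rng.uniform(0, box_y, n_lipids)
        z = np.where(leaflet > 0, 7.0, 3.0)
        frames[f] = np.column_stack([x, y, z])
    box = np.array([geom.X_box, box_y, 10.0])
    traj = _head_only_trajectory(
        frames, box, leaflet, geom, species=species
    )
    return traj, {
        "kind": "sorted_mix",
        "mode": mode,
        "minority_fraction": n_min / n_lipids,
        "n_lipids": n_lipids,
    }


def umbrella_harmonic(
    c: float = 5.0,
    x_min: float = 8.0,
    k_u: float = 200.0,
    centers: np.ndarray | None = None,
    n_samples: int = 5000,
    T: float = 310.0,
    seed: int = 0,
) -> tuple[list[UmbrellaWindow], dict]:
    """Umbrella windows drawn exactly from a harmonic landscape.

    The unbiased landscape is F*(x) = c/2 (x - x_min)^2; under window i
    the total potential is harmonic, so the biased distribution is the
    Gaussian with mean (c x_min + k_u c_i)/(c + k_u) and variance
    kBT/(c + k_u) — sampled directly (a Boltzmann oracle, no dynamics).
    """
    if centers is None:
        centers = np.linspace(x_min - 3.0, x_min + 3.0, 20)
    rng = np.random.default_rng(seed)
    kbt = KB * T
    var = kbt / (c + k_u)
    windows = []
    for ci in centers:
        mu = (c * x_min + k_u * ci) / (c + k_u)
        samples = rng.normal(mu, np.sqrt(var), n_samples)
        windows.append(UmbrellaWindow(center=float(ci), k_u=k_u, samples=samples))
    return windows, {
        "kind": "umbrella_harmonic",
        "c": c,
        "x_min": x_min,
        "k_u": k_u,
        "T": T,
        "n_samples": n_samples,
    }


FIXTURE_KINDS = {
    "flat_membrane": flat_membrane,
    "sigmoid_membrane": sigmoid_membrane,
    "defect_lattice": defect_lattice,
    "sorted_mix": sorted_mix,
    "umbrella_harmonic": umbrella_harmonic,
}


def make_fixture(kind: str, params: dict | None = None, seed: int = 0,
                 out_dir: str | Path | None = None):
    """Dispatch a fixture generator; optionally write files + truth JSON.

    Trajectory fixtures are written as multi-frame XYZ plus the truth
    sidecar; umbrella fixtures as one TSV per window.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(
            f"unregistered fixture kind {kind!r}; known: {sorted(FIXTURE_KINDS)}"
        )
    obj, truth = FIXTURE_KINDS[kind](**(params or {}), seed=seed)
    truth["seed"] = seed
    if out_dir is not None:
        from .io import write_json, write_tsv, write_xyz

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if isinstance(obj, Trajectory):
            names = np.where(obj.is_tail, "T", "H")
            write_xyz(out / f"{kind}.xyz", obj.frames, names, comment=kind)
        else:
            for i, w in enumerate(obj):
                write_tsv(
                    out / f"{kind}_window{i:03d}.tsv",
                    {"sample": np.arange(w.samples.size), "x_com": w.samples},
                    header_note=f"center={w.center} k_u={w.k_u}",
                )
        write_json(out / f"{kind}_truth.json", truth)
    return obj, truth
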