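"""Desk-scale study protocols: standard runs used by examples and tests.

The reference membrane geometry of the thinning protocol (55 nm box with
10 nm thin and buffer zones, ~4 nm thick bilayer) is far beyond what a
single CPU core samples in minutes, so the package ships a *desk-scale*
protocol: the same zone proportions on a 12 x 3.6 nm box of surrogate
lipids (~1000-1700 beads), with the squeeze amplitude D scaled to the
surrogate bilayer thickness (2.2 nm instead of 4 nm).  All quantitative
claims made for this protocol are sign/ordering properties, not the
reference system's magnitudes; docs/methods.md discusses what does and
does not transfer.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .builder import attach_probe, build_bilayer, build_probe
from .defects import DefectStats, detect_defects_trajectory, fit_size_constant
from .dynamics import RunSettings, Simulation, minimize
from .free_energy import (
    FreeEnergyProfile,
    SensingForce,
    plan_windows,
    run_window,
    sensing_force,
    wham,
)
from .geometry import ThinningFieldParams, ZoneGeometry
from .sorting import composition_histogram, zone_enrichment
from .system import Trajectory
from .thickness import ThicknessProfile, thickness_by_bin

__all__ = [
    "desk_geometry",
    "desk_field",
    "run_thinned_bilayer",
    "zone_thickness",
    "zone_defect_constants",
    "run_sorting_pair",
    "SORTING_PAIRS",
    "run_probe_sensing",
]

#: Desk-scale zone layout (nm): thin 3, buffers 2, normal 5 (wrapped).
DESK_GEOMETRY = dict(X_box=12.0, A_thin=3.0, A_buffer=2.0)
DESK_BOX_Y = 3.6
DESK_BOX_Z = 9.0
DESK_APL = 0.255  # tensionless area per lipid of the baseline species

#: Squeeze field for the desk-scale membrane: D scaled to the ~2.2 nm
#: surrogate bilayer as the reference D=1 nm is to the ~4 nm original.
DESK_FIELD = dict(k=20.0, D=0.6)

#: Binary mixtures for the sorting study: each pairs one thin-zone
#: depleted candidate with one enriched candidate at 15 mol% each.
SORTING_PAIRS = (
    {"POPC": 0.7, "POPE": 0.15, "LYPC": 0.15},
    {"POPC": 0.7, "CHOL": 0.15, "PLPC": 0.15},
)


def desk_geometry() -> ZoneGeometry:
    return ZoneGeometry(**DESK_GEOMETRY)


def desk_field(k: float | None = None, D: float | None = None) -> ThinningFieldParams:
    p = dict(DESK_FIELD)
    if k is not None:
        p["k"] = k
    if D is not None:
        p["D"] = D
    return ThinningFieldParams(**p)


def _build(seed: int, composition: dict[str, float] | None = None):
    geom = desk_geometry()
    system = build_bilayer(
        geom,
        composition or {"POPC": 1.0},
        area_per_lipid=DESK_APL,
        seed=seed,
        box_y=DESK_BOX_Y,
        box_z=DESK_BOX_Z,
    )
    minimize(system, n_steps=300)
    return geom, system


def run_thinned_bilayer(
    seed: int,
    k: float = DESK_FIELD["k"],
    composition: dict[str, float] | None = None,
    equil_steps: int = 14000,
    sample_steps: int = 16000,
    sample_every: int = 400,
) -> tuple[Trajectory, ZoneGeometry]:
    """Equilibrate a desk-scale bilayer under the squeeze field and sample.

    Returns the sampled trajectory and the geometry.  k = 0 runs the
    field-free control.
    """
    geom, system = _build(seed, composition)
    field = desk_field(k=k)
    sim = Simulation(system, RunSettings(seed=seed + 7919), field=field)
    sim.step(equil_steps)
    traj, _ = sim.run(sample_steps, sample_every=sample_every)
    return traj, geom


def zone_thickness(
    traj: Trajectory, geom: ZoneGeometry, n_bins: int = 24
) -> dict[str, tuple[float, float]]:
    """(mean, SE) head-to-head thickness for the thin and normal zones."""
    prof: ThicknessProfile = thickness_by_bin(traj, geom, n_bins)
    return {z: prof.zone_mean(geom, z) for z in ("thin", "normal")}


def zone_defect_constants(
    traj: Trajectory, A_min: float = 15.0, p_min: float = 1e-4, n_blocks: int = 10
) -> dict[str, DefectStats]:
    """Packing-defect size constants for the thin and normal zones."""
    out = {}
    for zone in ("thin", "normal"):
        areas = np.concatenate(detect_defects_trajectory(traj, zone))
        out[zone] = fit_size_constant(
            areas, A_min=A_min, p_min=p_min, n_blocks=n_blocks, zone=zone
        )
    return out


def run_sorting_pair(
    seed: int,
    composition: dict[str, float],
    equil_steps: int = 14000,
    sample_steps: int = 30000,
    sample_every: int = 500,
    n_bins: int = 24,
) -> dict[str, float]:
    """Thin-zone enrichment of each minority species in a binary-pair mix.

    Returns {species: thin-zone content normalized to its initial mole
    fraction}; 1.0 means no sorting.
    """
    geom, system = _build(seed, composition)
    sim = Simulation(
        system, RunSettings(seed=seed + 104729), field=desk_field()
    )
    sim.step(equil_steps)
    traj, _ = sim.run(sample_steps, sample_every=sample_every)
    hist = composition_histogram(traj, geom, n_bins=n_bins)
    return {
        sp: zone_enrichment(hist, geom, frac, sp)["thin"]
        for sp, frac in composition.items()
        if sp != "POPC"
    }


def run_probe_sensing(
    seed: int,
    window_span: tuple[float, float] = (2.25, 4.75),
    window_spacing: float = 0.25,
    k_u: float = 200.0,
    equil_steps: int = 4000,
    window_equil: int = 1000,
    window_steps: int = 2500,
    n_beads_per_row: int = 8,
) -> tuple[FreeEnergyProfile, SensingForce]:
    """Umbrella-sample the amphipathic probe across one buffer zone.

    Windows span from inside the normal zone (x ~ 2.25) across the left
    buffer into the thin-zone edge (x ~ 4.75); WHAM unbiases the COM
    histograms and the buffer-zone slope of F is the sensing force
    (positive = attraction toward the thin zone).
    """
    geom, system = _build(seed)
    probe = build_probe(
        n_beads_per_row,
        seed=seed,
        geom=geom,
        y_center=DESK_BOX_Y / 2,
        spacing=0.5,
        row_gap=0.55,
    )
    system = attach_probe(system, probe, seed=seed)
    minimize(system, n_steps=150)
    field = desk_field()
    sim = Simulation(system, RunSettings(seed=seed + 31), field=field)
    sim.step(equil_steps)
    # ladder from the thin-zone edge outward: the probe starts centered in
    # the thin zone, so windows are visited in decreasing x and each seeds
    # from the previous window's end state (sequential seeding)
    centers = plan_windows(window_span[1], window_span[0], window_spacing)
    windows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # drift warnings expected mid-buffer
        for i, c in enumerate(centers):
            windows.append(
                run_window(
                    system,
                    float(c),
                    k_u=k_u,
                    settings=RunSettings(seed=seed * 1009 + i),
                    field=field,
                    n_steps=window_steps,
                    equil_steps=window_equil,
                    sample_every=10,
                    in_place=True,
                )
            )
    profile = wham(windows, T=310.0, bin_width=0.1, min_overlap=0)
    force = sensing_force(profile, geom)
    return profile, force
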