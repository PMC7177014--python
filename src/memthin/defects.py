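"""Lipid packing defect detection and the exponential size constant.

A defect is a patch of the leaflet surface where hydrophobic tail beads
are exposed to the solvent side.  Detection rasterizes a zone of the
membrane onto an xy-grid (default 1 Angstrom spacing) and scans each cell
from the solvent side toward the bilayer midplane: the cell is a defect
cell iff the first bead whose xy-projected radius covers it is a tail
bead, or no bead covers it at all.  4-connected defect cells (periodic
in y) are clustered into defects whose area is counted in grid cells.

The defect-area distribution has an exponential tail p(A) ~ exp(-A/pi_c);
``fit_size_constant`` estimates the size constant pi_c as the negative
inverse slope of a weighted linear fit to ln p(A), restricted to
A >= A_min and p(A) >= p_min (the PackMem fitting rules), with a block-
averaged standard error.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

from .system import Trajectory

__all__ = ["DefectStats", "detect_defects", "detect_defects_trajectory", "fit_size_constant"]

#: Default grid spacing in nm (1 Angstrom, the PackMem convention).
GRID_SPACING = 0.1


@njit(cache=True)
def _rasterize(px, py, pz, radii, tail, x0, nx, ny, spacing, ly, top_z, top_tail):
    """Project beads onto the grid keeping, per cell, the topmost cover.

    ``top_z`` is initialized to -inf; after the call, cells with
    ``top_z == -inf`` are uncovered.  y wraps periodically; x does not
    (the zone is an x-slab)."""
    for b in range(px.shape[0]):
        r = radii[b]
        gx_lo = int(np.floor((px[b] - r - x0) / spacing))
        gx_hi = int(np.ceil((px[b] + r - x0) / spacing))
        gy_lo = int(np.floor((py[b] - r) / spacing))
        gy_hi = int(np.ceil((py[b] + r) / spacing))
        r2 = r * r
        for ix in range(gx_lo, gx_hi + 1):
            if ix < 0 or ix >= nx:
                continue
            cx = x0 + (ix + 0.5) * spacing
            dx = px[b] - cx
            for iy in range(gy_lo, gy_hi + 1):
                cy = (iy + 0.5) * spacing
                dy = py[b] - cy
                dy -= ly * np.rint(dy / ly)
                iyw = iy % ny
                if dx * dx + dy * dy <= r2:
                    if pz[b] > top_z[ix, iyw]:
                        top_z[ix, iyw] = pz[b]
                        top_tail[ix, iyw] = tail[b]


def _cluster_areas(defect_mask: np.ndarray, spacing: float) -> np.ndarray:
    """Areas (nm^2 -> returned in Angstrom^2) of 4-connected clusters,
    merged across the periodic y boundary."""
    labels, n = ndimage.label(defect_mask)  # default structure = 4-connectivity
    if n == 0:
        return np.empty(0)
    # merge clusters touching across the y wrap
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    first, last = labels[:, 0], labels[:, -1]
    for a, b in zip(first, last):
        if a > 0 and b > 0 and a != b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(a) for a in range(n + 1)])
    counts = np.bincount(roots[labels.ravel()], minlength=n + 1)[1:]
    counts = counts[counts > 0]
    return counts * (spacing * 10.0) ** 2  # cell area in Angstrom^2


def detect_defects(
    pos: np.ndarray,
    radii: np.ndarray,
    is_tail: np.ndarray,
    leaflet_mask: np.ndarray,
    zone_x: tuple[float, float],
    box: np.ndarray,
    midplane_z: float,
    upper: bool = True,
    grid_spacing: float = GRID_SPACING,
) -> np.ndarray:
    """Defect areas (Angstrom^2) on one leaflet within an x-slab of one frame.

    ``leaflet_mask`` selects the beads belonging to the analyzed leaflet
    (its lipids' head *and* tail beads).  Beads on the far side of the
    midplane are ignored; for the lower leaflet the frame is mirrored in
    z so the same solvent-side scan applies.
    """
    x_lo, x_hi = zone_x
    if x_hi - x_lo < 3 * grid_spacing:
        raise ValueError("zone narrower than 3 grid cells")
    lx, ly = float(box[0]), float(box[1])
    m = leaflet_mask.copy()
    z = pos[:, 2] - midplane_z
    if not upper:
        z = -z
    m &= z > 0  # solvent side of the midplane only
    # include beads whose disk can reach into the zone, honoring the
    # periodic wrap in x, and unwrap their x into the window frame
    pad = radii.max() if radii.size else 0.0
    center = 0.5 * (x_lo + x_hi)
    rel = np.mod(pos[:, 0] - center + lx / 2, lx) - lx / 2
    m &= np.abs(rel) < 0.5 * (x_hi - x_lo) + pad
    px = center + rel
    nx = int(round((x_hi - x_lo) / grid_spacing))
    ny = int(round(ly / grid_spacing))
    top_z = np.full((nx, ny), -np.inf)
    top_tail = np.zeros((nx, ny), dtype=np.bool_)
    _rasterize(
        px[m].astype(np.float64),
        pos[m, 1].astype(np.float64),
        z[m].astype(np.float64),
        radii[m].astype(np.float64),
        is_tail[m].astype(np.bool_),
        x_lo,
        nx,
        ny,
        grid_spacing,
        ly,
        top_z,
        top_tail,
    )
    defect = top_tail | np.isinf(top_z)  # tail on top, or bare down to midplane
    return _cluster_areas(defect, grid_spacing)


def detect_defects_trajectory(
    traj: Trajectory,
    zone: str,
    grid_spacing: float = GRID_SPACING,
) -> list[np.ndarray]:
    """Per-frame defect areas pooled over both leaflets for a named zone.

    ``zone`` is 'thin' or 'normal'; the zone x-ranges come from the
    trajectory's geometry.  Returns a list of per-frame area arrays."""
    geom = traj.geom
    if zone == "thin":
        ranges = [geom.thin_range()]
    elif zone == "normal":
        ranges = geom.normal_ranges()
    else:
        raise ValueError(f"unknown zone {zone!r}")
    # clusters truncate at window edges, so thin and normal zones must be
    # scanned with equal-width windows for their size statistics to compare
    w = min(
        geom.A_thin, min(hi - lo for lo, hi in geom.normal_ranges())
    )
    ranges = [
        ((lo + hi) / 2 - w / 2, (lo + hi) / 2 + w / 2) for lo, hi in ranges
    ]
    lipid = traj.lipid_id >= 0
    out = []
    for f in range(traj.n_frames):
        pos = traj.frames[f]
        mid = float(pos[lipid, 2].mean())
        areas = []
        for leaf, upper in ((1, True), (-1, False)):
            lm = lipid & (traj.leaflet == leaf)
            for x_rng in ranges:
                areas.append(
                    detect_defects(
                        pos,
                        traj.radii,
                        traj.is_tail,
                        lm,
                        x_rng,
                        traj.box,
                        mid,
                        upper=upper,
                        grid_spacing=grid_spacing,
                    )
                )
        out.append(np.concatenate(areas) if areas else np.empty(0))
    return out


@dataclass
class DefectStats:
    """Exponential size-constant estimate for one zone.

    ``size_constant`` comes from the weighted ln p(A) fit on the pooled
    histogram (small per-block samples carry a sizable zero-truncation
    bias, so blocks provide the *error*, not the value): the fit A-range
    is fixed from the pooled histogram, each block is refitted over that
    range, and the SE is the block spread / sqrt(n_blocks).
    """

    zone: str
    areas: np.ndarray
    size_constant: float  # pooled-fit value, Angstrom^2
    size_constant_se: float  # block-averaged standard error
    block_mean: float  # mean of per-block fits (diagnostic)
    n_blocks: int
    fit_range: tuple[float, float]
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "zone": self.zone,
            "n_defects": int(self.areas.size),
            "size_constant": self.size_constant,
            "size_constant_se": self.size_constant_se,
            "block_mean": self.block_mean,
            "n_blocks": self.n_blocks,
            "fit_range": list(self.fit_range),
            "degenerate": self.degenerate,
        }


def _weighted_logfit(
    areas: np.ndarray,
    A_lo: float,
    A_hi: float,
    bin_width: float,
    min_points: int = 4,
) -> float:
    """Inverse negative slope of the count-weighted fit of ln p(A) vs A
    over the fixed range [A_lo, A_hi] (empty bins drop out of the fit)."""
    edges = np.arange(0.0, areas.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(areas, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    m = (centers >= A_lo) & (centers <= A_hi) & (counts > 0)
    if m.sum() < min_points:
        raise ValueError(
            f"only {int(m.sum())} usable histogram points after thresholds"
        )
    x, lnp, w = centers[m], np.log(p[m]), counts[m].astype(float)
    xbar = np.sum(w * x) / w.sum()
    ybar = np.sum(w * lnp) / w.sum()
    slope = np.sum(w * (x - xbar) * (lnp - ybar)) / np.sum(w * (x - xbar) ** 2)
    if slope >= 0:
        raise ValueError("non-decaying defect-area distribution")
    return -1.0 / slope


def fit_size_constant(
    areas: np.ndarray,
    A_min: float = 15.0,
    p_min: float = 1e-4,
    n_blocks: int = 10,
    bin_width: float = 1.0,
    zone: str = "",
) -> DefectStats:
    """Estimate the defect size constant with a block-averaged error.

    ``areas`` are pooled defect areas in Angstrom^2 (>= 100 required).
    The histogram uses ``bin_width`` (default one 1-Angstrom grid cell);
    the weighted linear fit of ln p(A) uses bins with A >= A_min and
    empirical p >= p_min.  The fit range determined on the pooled
    histogram is reused for the per-block refits that give the SE.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < 100:
        raise ValueError(f"need >= 100 defect areas, got {areas.size}")
    if np.ptp(areas) < 1e-12:
        return DefectStats(
            zone, areas, float(areas[0]), 0.0, float(areas[0]), n_blocks,
            (A_min, areas.max()), degenerate=True,
        )
    # fit range from the pooled histogram thresholds
    edges = np.arange(0.0, areas.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(areas, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()
    m = (centers >= A_min) & (p >= p_min)
    if m.sum() < 4:
        raise ValueError(
            f"only {int(m.sum())} usable histogram points after thresholds"
        )
    A_lo, A_hi = float(centers[m].min()), float(centers[m].max())
    pooled = _weighted_logfit(areas, A_lo, A_hi, bin_width)
    block_vals = []
    for block in np.array_split(areas, n_blocks):
        try:
            block_vals.append(_weighted_logfit(block, A_lo, A_hi, bin_width))
        except ValueError:
            continue
    if len(block_vals) < 2:
        raise ValueError("too few blocks with enough statistics for an SE")
    bv = np.asarray(block_vals)
    return DefectStats(
        zone=zone,
        areas=areas,
        size_constant=float(pooled),
        size_constant_se=float(bv.std(ddof=1) / np.sqrt(bv.size)),
        block_mean=float(bv.mean()),
        n_blocks=len(block_vals),
        fit_range=(A_lo, A_hi),
    )
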