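"""Thinness-induced lipid sorting: composition histograms and enrichment.

Lipid positions are taken as the head-bead x-coordinate (consistent with
the thickness analysis).  ``composition_histogram`` bins lipids along x
(50 bins by default) and averages species mole fractions over frames and
replicas; ``zone_enrichment`` reduces the histogram to per-zone content
normalized to the initial mole fraction, so 1.0 means no sorting, values
below 1 depletion and above 1 enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ZoneGeometry
from .system import Trajectory

__all__ = ["CompositionHistogram", "composition_histogram", "zone_enrichment"]


@dataclass
class CompositionHistogram:
    """Per-bin, per-species mole fractions averaged over frames.

    ``counts`` is a (n_bins, n_species) table of lipid counts summed over
    frames; ``fractions`` normalizes each bin over the species present.
    Bins that never held a lipid are flagged in ``empty``.
    """

    bin_centers: np.ndarray
    species: list[str]
    counts: np.ndarray
    n_frames: int

    @property
    def fractions(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.counts / tot, np.nan)

    @property
    def empty(self) -> np.ndarray:
        return self.counts.sum(axis=1) == 0

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions
        rows = []
        for j, sp in enumerate(self.species):
            for i, c in enumerate(self.bin_centers):
                rows.append(
                    {
                        "bin_center": c,
                        "species": sp,
                        "fraction": frac[i, j],
                        "count": self.counts[i, j],
                    }
                )
        return pd.DataFrame(rows)


def composition_histogram(
    trajectories: Trajectory | list[Trajectory],
    geom: ZoneGeometry,
    n_bins: int = 50,
) -> CompositionHistogram:
    """Species content in ``n_bins`` bins along x, pooled over frames.

    Accepts a single trajectory or a list of replicas; replica data are
    pooled frame-weighted before normalization.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories or trajectories[0].n_frames < 1:
        raise ValueError("need at least one frame")
    species = sorted(
        set().union(*(set(t.species_of_lipid.tolist()) for t in trajectories))
    )
    sp_index = {s: j for j, s in enumerate(species)}
    counts = np.zeros((n_bins, len(species)), dtype=np.int64)
    n_frames = 0
    for traj in trajectories:
        lx = geom.X_box
        for f in range(traj.n_frames):
            x, labels = traj.lipid_head_x(f)
            bi = np.minimum(
                (np.mod(x, lx) / lx * n_bins).astype(np.int64), n_bins - 1
            )
            for b, s in zip(bi, labels):
                counts[b, sp_index[s]] += 1
            n_frames += 1
    edges = np.linspace(0.0, geom.X_box, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return CompositionHistogram(centers, species, counts, n_frames)


def _zone_overlap(lo: float, hi: float, geom: ZoneGeometry, zone: str) -> float:
    """Length of [lo, hi) overlapping the named zone (box coordinates)."""
    if zone == "thin":
        ranges = [geom.thin_range()]
    elif zone == "normal":
        ranges = geom.normal_ranges()
    elif zone == "buffer":
        t0, t1 = geom.thin_range()
        ranges = [(t0 - geom.A_buffer, t0), (t1, t1 + geom.A_buffer)]
    else:
        raise ValueError(f"unknown zone {zone!r}")
    return sum(max(0.0, min(hi, b) - max(lo, a)) for a, b in ranges)


def zone_enrichment(
    hist: CompositionHistogram,
    geom: ZoneGeometry,
    initial_fraction: float,
    species: str,
    zones: tuple[str, ...] = ("thin", "normal"),
) -> dict[str, float]:
    """Zone content of one species normalized to its initial mole fraction.

    Bins straddling a zone boundary contribute in proportion to their
    overlap length.  Buffer bins are reported separately (request the
    'buffer' zone explicitly); enrichment(zone) = zone mole fraction /
    ``initial_fraction``.
    """
    if initial_fraction <= 0:
        raise ValueError("initial_fraction must be > 0")
    if species not in hist.species:
        raise ValueError(f"species {species!r} not in histogram")
    j = hist.species.index(species)
    n_bins = hist.bin_centers.size
    w = geom.X_box / n_bins
    out: dict[str, float] = {}
    for zone in zones:
        weights = np.array(
            [
                _zone_overlap(c - w / 2, c + w / 2, geom, zone) / w
                for c in hist.bin_centers
            ]
        )
        sp = float(np.sum(weights * hist.counts[:, j]))
        tot = float(np.sum(weights * hist.counts.sum(axis=1)))
        if tot == 0:
            out[zone] = np.nan
            continue
        out[zone] = (sp / tot) / initial_fraction
    return out
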