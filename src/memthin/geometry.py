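"""Zone geometry and the membrane-thinning external force.

The simulation box is partitioned along x into a centered *thin* zone of
length ``A_thin``, two flanking *buffer* zones of length ``A_buffer``, and
the remaining *normal* zone, which is contiguous across the periodic
boundary.  A harmonic squeeze force

    F_z = d * C(x) * k * (D/2 - |z|)

acts on lipid tail beads whose distance |z| from the bilayer midplane
exceeds D/2.  The direction constant d (+1 above, -1 below, 0 inside the
slab of half-width D/2) always points the force toward the midplane, and
the zone factor C(x) ramps linearly from 1 in the thin zone to 0 at the
buffer/normal boundary.

Note that F_z depends on x only through C(x) yet has no x-component, so
the field is *not* the gradient of a scalar potential; it is applied as a
bare force and excluded from reported potential energies.  The Langevin
thermostat absorbs the small net work it performs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZoneGeometry",
    "ThinningFieldParams",
    "zone_scaling",
    "direction_constant",
    "thinning_force",
    "zone_scaling_array",
    "thinning_force_array",
]


class ConfigurationError(ValueError):
    """Raised for geometrically impossible zone layouts or bad field parameters."""


@dataclass(frozen=True)
class ZoneGeometry:
    """Partition of the box x-axis into thin / buffer / normal zones.

    Parameters
    ----------
    X_box : float
        Box length along x (nm).
    A_thin : float
        Length of the centered thin zone (nm).
    A_buffer : float
        Length of each of the two buffer zones (nm).

    The thin-zone center ``x_c`` is derived as ``X_box / 2``; the normal
    zone wraps contiguously across the periodic boundary.
    """

    X_box: float
    A_thin: float
    A_buffer: float
    x_c: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.X_box > 0 and np.isfinite(self.X_box)):
            raise ConfigurationError(f"X_box must be positive, got {self.X_box}")
        if self.A_thin <= 0 or self.A_buffer <= 0:
            raise ConfigurationError(
                f"zone lengths must be positive (A_thin={self.A_thin}, "
                f"A_buffer={self.A_buffer})"
            )
        if self.A_thin + 2 * self.A_buffer > self.X_box + 1e-12:
            raise ConfigurationError(
                f"A_thin + 2*A_buffer = {self.A_thin + 2 * self.A_buffer} "
                f"exceeds X_box = {self.X_box}"
            )
        object.__setattr__(self, "x_c", self.X_box / 2.0)

    # -- zone boundaries (distances from x_c) --------------------------------
    @property
    def thin_half(self) -> float:
        """Half-width of the thin zone (nm)."""
        return self.A_thin / 2.0

    @property
    def buffer_edge(self) -> float:
        """Distance from x_c to the buffer/normal boundary (nm)."""
        return self.A_thin / 2.0 + self.A_buffer

    def wrap_x(self, x: np.ndarray | float) -> np.ndarray | float:
        """Wrap x into [0, X_box)."""
        return np.mod(x, self.X_box)

    def zone_of(self, x: float) -> str:
        """Classify a wrapped coordinate as 'thin', 'buffer' or 'normal'."""
        dx = abs(float(self.wrap_x(x)) - self.x_c)
        if dx <= self.thin_half:
            return "thin"
        if dx < self.buffer_edge:
            return "buffer"
        return "normal"

    def thin_range(self) -> tuple[float, float]:
        """The thin-zone x interval (x_c - A_thin/2, x_c + A_thin/2)."""
        return (self.x_c - self.thin_half, self.x_c + self.thin_half)

    def normal_ranges(self) -> list[tuple[float, float]]:
        """The normal-zone x intervals inside [0, X_box)."""
        lo = self.x_c - self.buffer_edge
        hi = self.x_c + self.buffer_edge
        out = []
        if lo > 0:
            out.append((0.0, lo))
        if hi < self.X_box:
            out.append((hi, self.X_box))
        return out


@dataclass(frozen=True)
class ThinningFieldParams:
    """Harmonic thinning-field parameters.

    k : force constant (kJ mol^-1 nm^-2); 0 switches the squeeze off.
    D : minimal-thickness parameter (nm); no force acts within |z| < D/2.

    Defaults follow the reference setup: k = 20 kJ nm^-2 mol^-1, D = 1 nm.
    """

    k: float = 20.0
    D: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ConfigurationError(f"k must be >= 0, got {self.k}")
        if self.D <= 0:
            raise ConfigurationError(f"D must be > 0, got {self.D}")


def zone_scaling(x: float, geom: ZoneGeometry) -> float:
    """Zone scale factor C(x) in [0, 1].

    C = 1 inside the thin zone, 0 in the normal zone, and ramps linearly
    across each buffer zone; continuous everywhere, periodic in x.
    """
    dx = abs(float(geom.wrap_x(x)) - geom.x_c)
    if dx <= geom.thin_half:
        return 1.0
    if dx >= geom.buffer_edge:
        return 0.0
    return (geom.buffer_edge - dx) / geom.A_buffer


def zone_scaling_array(x: np.ndarray, geom: ZoneGeometry) -> np.ndarray:
    """Vectorized :func:`zone_scaling`."""
    dx = np.abs(np.mod(x, geom.X_box) - geom.x_c)
    c = (geom.buffer_edge - dx) / geom.A_buffer
    return np.clip(c, 0.0, 1.0)


def direction_constant(z: float, D: float) -> int:
    """Direction constant d of the squeeze force.

    +1 above the midplane slab (z > D/2), -1 below (z < -D/2), 0 inside.
    """
    if z > D / 2.0:
        return 1
    if z < -D / 2.0:
        return -1
    return 0


def thinning_force(
    z: float,
    C: float,
    params: ThinningFieldParams,
    is_tail: bool = True,
) -> float:
    """z-component of the thinning force on one bead (kJ mol^-1 nm^-1).

    ``z`` is the signed distance from the bilayer midplane.  The force is
    F_z = d * C * k * (D/2 - |z|), zero for non-tail beads and inside the
    minimal-thickness slab, and always restoring (toward the midplane).
    """
    if not is_tail or not params.enabled:
        return 0.0
    if not np.isfinite(z):
        raise RuntimeError(f"non-finite bead coordinate z={z}")
    d = direction_constant(z, params.D)
    return d * C * params.k * (params.D / 2.0 - abs(z))


def thinning_force_array(
    x: np.ndarray,
    z: np.ndarray,
    geom: ZoneGeometry,
    params: ThinningFieldParams,
    is_tail: np.ndarray,
) -> np.ndarray:
    """Vectorized thinning force for per-bead coordinates.

    ``z`` is measured from the bilayer midplane.  Returns the z-force per
    bead; x and y components are identically zero.
    """
    if not params.enabled or params.k == 0.0:
        return np.zeros_like(z)
    if not np.all(np.isfinite(z)):
        bad = np.flatnonzero(~np.isfinite(z))
        raise RuntimeError(f"non-finite z coordinates at bead indices {bad[:10]}")
    C = zone_scaling_array(x, geom)
    halfD = params.D / 2.0
    d = np.where(z > halfD, 1.0, np.where(z < -halfD, -1.0, 0.0))
    f = d * C * params.k * (halfD - np.abs(z))
    return np.where(is_tail, f, 0.0)
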