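"""Membrane thickness profile along x and the buffer-zone sigmoid fit.

Thickness is the head-to-head distance between leaflets: per x-bin and
frame, the mean z of upper-leaflet head beads minus the mean z of
lower-leaflet head beads.  The profile can be symmetrized about the
thin-zone center and its buffer-zone part fitted with the logistic
sigmoid

    a(xi) = L / (1 + exp(-kappa (xi - x0))) + b

where ``xi`` is the outward distance from the *thin-zone edge* (xi = 0 at
the thin/buffer boundary, increasing toward the normal zone).  With this
convention the reference parameter set has negative L and kappa: the
profile rises from the thin plateau b + L to the normal-zone baseline b.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import ZoneGeometry
from .system import Trajectory

__all__ = [
    "ThicknessProfile",
    "SigmoidFit",
    "sigmoid",
    "thickness_by_bin",
    "symmetrize",
    "fit_sigmoid",
]


@dataclass
class ThicknessProfile:
    """Binned head-to-head thickness along x (or along the half-box
    coordinate after symmetrization)."""

    bin_centers: np.ndarray
    mean_thickness: np.ndarray
    std_thickness: np.ndarray
    n_samples: np.ndarray

    @property
    def defined(self) -> np.ndarray:
        """Mask of bins where both leaflets contributed samples."""
        return self.n_samples > 0

    def zone_mean(self, geom: ZoneGeometry, zone: str) -> tuple[float, float]:
        """(mean, SE over bins) of thickness in the named zone; bin centers
        are interpreted as box coordinates."""
        zones = np.array([geom.zone_of(x) for x in self.bin_centers])
        m = (zones == zone) & self.defined
        if not m.any():
            raise ValueError(f"no defined bins in zone {zone!r}")
        vals = self.mean_thickness[m]
        se = vals.std(ddof=1) / np.sqrt(m.sum()) if m.sum() > 1 else 0.0
        return float(vals.mean()), float(se)


@dataclass
class SigmoidFit:
    """Fitted sigmoid parameters a(xi) = L/(1+exp(-kappa (xi-x0))) + b."""

    L: float
    kappa: float
    x0: float
    b: float
    cov: np.ndarray
    rms: float
    degenerate: bool = False

    def __call__(self, xi: np.ndarray | float) -> np.ndarray | float:
        return sigmoid(xi, self.L, self.kappa, self.x0, self.b)

    def thin_asymptote(self) -> float:
        return self.b + self.L

    def as_dict(self) -> dict:
        return {
            "L": self.L,
            "kappa": self.kappa,
            "x0": self.x0,
            "b": self.b,
            "cov": self.cov.tolist(),
            "rms": self.rms,
            "degenerate": self.degenerate,
        }


def sigmoid(
    xi: np.ndarray | float, L: float, kappa: float, x0: float, b: float
) -> np.ndarray | float:
    """Logistic sigmoid used for the buffer-zone thickness profile."""
    with np.errstate(over="ignore"):
        return L / (1.0 + np.exp(-kappa * (np.asarray(xi, float) - x0))) + b


def thickness_by_bin(
    traj: Trajectory, geom: ZoneGeometry, n_bins: int | None = None
) -> ThicknessProfile:
    """Per-bin leaflet-surface distance, averaged over frames.

    For each x-bin and frame the local upper and lower leaflet surfaces
    are the mean z of the respective head beads in that bin; thickness is
    their difference.  Bins where either leaflet has no head bead in a
    frame contribute no sample for that frame; bins empty in every frame
    are flagged by ``n_samples == 0``.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    if n_bins is None:
        n_bins = 110  # default bin width X_box/110 (~0.5 nm at reference size)
    edges = np.linspace(0.0, geom.X_box, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sums = np.zeros(n_bins)
    sq = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for f in range(traj.n_frames):
        x, z, leaf = traj.head_xz(f)
        x = np.mod(x, geom.X_box)
        bi = np.minimum((x / geom.X_box * n_bins).astype(np.int64), n_bins - 1)
        for b in np.unique(bi):
            sel = bi == b
            zu = z[sel][leaf[sel] > 0]
            zl = z[sel][leaf[sel] < 0]
            if zu.size == 0 or zl.size == 0:
                continue
            t = zu.mean() - zl.mean()
            sums[b] += t
            sq[b] += t * t
            counts[b] += 1
    mean = np.full(n_bins, np.nan)
    std = np.full(n_bins, np.nan)
    ok = counts > 0
    mean[ok] = sums[ok] / counts[ok]
    var = np.zeros(n_bins)
    many = counts > 1
    var[many] = (sq[many] - counts[many] * mean[many] ** 2) / (counts[many] - 1)
    std[ok] = np.sqrt(np.maximum(var[ok], 0.0))
    return ThicknessProfile(centers, mean, std, counts)


def symmetrize(profile: ThicknessProfile, geom: ZoneGeometry) -> ThicknessProfile:
    """Fold the full-box profile about the thin-zone center x_c.

    Output bin ``j`` holds the average of the two bins at distance
    delta_j on either side of x_c (sample-count weighted); its coordinate
    is delta_j, the outward distance from x_c.  Length is
    ``ceil(n_bins / 2)``.
    """
    n = profile.bin_centers.size
    half = (n + 1) // 2
    # pair bin x_c + delta with x_c - delta; bins are assumed to tile
    # [0, X_box) uniformly so index n//2 + j mirrors n//2 - 1 - j (even n)
    centers = np.empty(half)
    mean = np.full(half, np.nan)
    std = np.full(half, np.nan)
    nsamp = np.zeros(half, dtype=np.int64)
    w = geom.X_box / n
    for j in range(half):
        if n % 2 == 0:
            i_hi, i_lo = n // 2 + j, n // 2 - 1 - j
            delta = (j + 0.5) * w
        else:
            i_hi, i_lo = n // 2 + j, n // 2 - j
            delta = j * w
        centers[j] = delta
        pair = [i for i in (i_hi, i_lo) if 0 <= i < n]
        if n % 2 == 1 and j == 0:
            pair = [n // 2]
        cnts = profile.n_samples[pair]
        if cnts.sum() == 0:
            continue
        vals = profile.mean_thickness[pair]
        ok = cnts > 0
        nsamp[j] = cnts.sum()
        mean[j] = vals[ok].mean()  # plain pairwise mean of the two sides
        std[j] = profile.std_thickness[pair][ok].mean()
    return ThicknessProfile(centers, mean, std, nsamp)


def buffer_zone_points(
    profile: ThicknessProfile, geom: ZoneGeometry, symmetrized: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """(xi, thickness) samples restricted to the buffer zone.

    ``xi`` is the outward distance from the thin-zone edge.  For a
    symmetrized profile the bin coordinate is the distance from x_c; for
    a full-box profile both buffer zones are folded.
    """
    c = profile.bin_centers
    if symmetrized:
        delta = c
    else:
        delta = np.abs(np.mod(c, geom.X_box) - geom.x_c)
    m = (
        (delta > geom.thin_half)
        & (delta < geom.buffer_edge)
        & profile.defined
        & np.isfinite(profile.mean_thickness)
    )
    return delta[m] - geom.thin_half, profile.mean_thickness[m]


def fit_sigmoid(
    xi: np.ndarray,
    thickness: np.ndarray,
    A_buffer: float | None = None,
    max_restarts: int = 4,
) -> SigmoidFit:
    """Least-squares logistic fit of the buffer-zone thickness samples.

    Initialization: b from the normal-side mean, L from the thin-minus-
    normal difference, x0 at the buffer midpoint, kappa = +-4/A_buffer
    with both signs tried; the better least-squares solution wins.
    Raises RuntimeError on non-convergence after bounded restarts.
    """
    xi = np.asarray(xi, float)
    y = np.asarray(thickness, float)
    if xi.size < 8:
        raise ValueError(f"need >= 8 buffer-zone samples, got {xi.size}")
    if A_buffer is None:
        A_buffer = float(xi.max() - xi.min()) or 1.0
    span = y.max() - y.min()
    if span < 1e-6 or span < 0.02 * abs(y.mean()):
        # flat profile: no resolvable amplitude
        return SigmoidFit(
            L=0.0,
            kappa=0.0,
            x0=float(xi.mean()),
            b=float(y.mean()),
            cov=np.zeros((4, 4)),
            rms=float(np.sqrt(np.mean((y - y.mean()) ** 2))),
            degenerate=True,
        )
    lo = np.argsort(xi)[: max(3, xi.size // 4)]
    hi = np.argsort(xi)[-max(3, xi.size // 4):]
    b0 = float(y[hi].mean())  # normal-zone side (large xi)
    L0 = float(y[lo].mean() - b0)  # thin side minus normal side
    x0_0 = float(0.5 * (xi.min() + xi.max()))
    best = None
    last_err: Exception | None = None
    for sign in (-1.0, 1.0):
        for attempt in range(max_restarts):
            k0 = sign * 4.0 / A_buffer * (2.0**attempt)
            try:
                popt, pcov = curve_fit(
                    sigmoid,
                    xi,
                    y,
                    p0=[L0, k0, x0_0, b0],
                    maxfev=20000,
                )
            except RuntimeError as err:  # no convergence this start
                last_err = err
                continue
            resid = y - sigmoid(xi, *popt)
            ssq = float(np.sum(resid**2))
            if best is None or ssq < best[0]:
                best = (ssq, popt, pcov)
    if best is None:
        raise RuntimeError(f"sigmoid fit did not converge: {last_err}")
    ssq, popt, pcov = best
    L, kappa, x0, b = (float(v) for v in popt)
    # canonical orientation: report the branch with L <= 0 (profile rises
    # from the thin plateau); the two sign conventions are equivalent via
    # (L, kappa, b) -> (-L, -kappa, b + L)
    if L > 0:
        L, kappa, b = -L, -kappa, b + L
    return SigmoidFit(
        L=L,
        kappa=kappa,
        x0=x0,
        b=b,
        cov=np.asarray(pcov),
        rms=float(np.sqrt(ssq / xi.size)),
    )


def fit_profile_sigmoid(
    profile: ThicknessProfile, geom: ZoneGeometry, symmetrized: bool = True
) -> SigmoidFit:
    """Convenience wrapper: restrict to the buffer zone, then fit."""
    xi, y = buffer_zone_points(profile, geom, symmetrized=symmetrized)
    return fit_sigmoid(xi, y, A_buffer=geom.A_buffer)
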