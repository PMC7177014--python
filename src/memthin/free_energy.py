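"""Umbrella sampling along x, WHAM unbiasing and the defect-sensing force.

The probe's center of mass is dragged through a ladder of harmonic
umbrella windows spanning the buffer zone; the weighted histogram
analysis method (WHAM) combines the biased position histograms into one
unbiased free-energy profile F(x).  The slope of a linear fit to F(x)
over the buffer zone is the mean force pulling the probe toward the thin
(defect-rich) region; combined with the sigmoid thickness profile a(x),
F can be re-expressed as a function of local membrane thickness F(a).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ComRestraint, RunSettings, Simulation
from .geometry import ThinningFieldParams, ZoneGeometry
from .system import MembraneSystem
from .thickness import SigmoidFit
from .units import KB, kj_per_mol_nm_to_pn

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "plan_windows",
    "run_window",
    "wham",
    "sensing_force",
    "convert_force",
    "to_kbt",
    "reparameterize_thickness",
]


@dataclass
class UmbrellaWindow:
    """One umbrella window: restraint center, stiffness and COM samples."""

    center: float
    k_u: float
    samples: np.ndarray
    equilibration_cut: int = 0

    def __post_init__(self) -> None:
        if self.k_u <= 0:
            raise ValueError("k_u must be > 0")
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def production(self) -> np.ndarray:
        s = self.samples[self.equilibration_cut:]
        if s.size < 100:
            raise ValueError(
                f"window at {self.center}: only {s.size} post-cut samples (< 100)"
            )
        return s


@dataclass
class FreeEnergyProfile:
    """Unbiased free energy F(x) on a grid, anchored at min(F) = 0."""

    x: np.ndarray
    F: np.ndarray
    support: np.ndarray  # total histogram counts per bin
    n_iterations: int = 0

    def interp(self, xq: np.ndarray | float) -> np.ndarray | float:
        m = self.support > 0
        return np.interp(xq, self.x[m], self.F[m])


def plan_windows(x_start: float, x_end: float, spacing: float) -> np.ndarray:
    """Inclusive arithmetic ladder of window centers.

    The range must be commensurate with the spacing (to 1e-9); the count
    is round(|x_start - x_end| / spacing) + 1.  The reference protocol
    (27.5 -> 5.5 nm at 0.2 nm) gives 111 windows.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    span = abs(x_end - x_start)
    if span == 0:
        raise ValueError("x_start and x_end coincide")
    n_steps = round(span / spacing)
    if abs(span - n_steps * spacing) > 1e-9 * max(1.0, span):
        raise ValueError(
            f"range {span} not commensurate with spacing {spacing}"
        )
    step = spacing if x_end > x_start else -spacing
    return x_start + step * np.arange(n_steps + 1)


def run_window(
    system: MembraneSystem,
    center: float,
    k_u: float = 1000.0,
    settings: RunSettings | None = None,
    field: ThinningFieldParams | None = None,
    n_steps: int = 5000,
    equil_steps: int = 1000,
    sample_every: int = 10,
    in_place: bool = False,
) -> UmbrellaWindow:
    """Sample one umbrella window on a (copy of a) probe-bearing system.

    A harmonic restraint -k_u (x_com - center) acts on the probe's
    mass-weighted COM in x only; y and z stay unrestrained.  The COM
    series is logged every ``sample_every`` steps after ``equil_steps``
    equilibration steps.  A warning is attached if the mean COM drifts
    more than 3 sqrt(kBT / k_u) from the center (poor window overlap).
    """
    if system.probe_indices.size == 0:
        raise ValueError("system has no probe attached")
    if settings is None:
        settings = RunSettings()
    lx = float(system.box[0])
    if not 0 <= center <= lx:
        raise ValueError(f"window center {center} outside box [0, {lx}]")
    work = system if in_place else system.snapshot()
    restraint = ComRestraint(work.probe_indices, center, k_u)
    sim = Simulation(work, settings, field=field, restraints=[restraint])
    sim.step(equil_steps)
    samples = []
    for _ in range(n_steps // sample_every):
        sim.step(sample_every)
        samples.append(restraint.com_x(work.pos, work.mass, lx))
    window = UmbrellaWindow(center=center, k_u=k_u, samples=np.asarray(samples))
    drift = abs(window.samples.mean() - center)
    if drift > 3.0 * np.sqrt(KB * settings.T / k_u):
        import warnings

        warnings.warn(
            f"window at {center:.2f} nm: COM drifted {drift:.3f} nm from the "
            "center; histogram overlap may be poor",
            stacklevel=2,
        )
    return window


def wham(
    windows: list[UmbrellaWindow],
    grid: np.ndarray | None = None,
    T: float = 310.0,
    tol: float = 1e-7,
    max_iter: int = 100000,
    bin_width: float = 0.05,
    min_overlap: int = 10,
) -> FreeEnergyProfile:
    """Self-consistent WHAM over the window histograms.

    Iterates P(x_b) = sum_i n_i(x_b) / sum_i N_i exp((f_i - U_i(x_b))/kBT)
    with window free energies f_i updated from P until the largest change
    in f_i/kBT is below ``tol``; F(x) = -kBT ln P(x), min-anchored.
    Adjacent windows sharing fewer than ``min_overlap`` counts trigger a
    warning; non-convergence raises with the residual.
    """
    if not windows:
        raise ValueError("no umbrella windows")
    beta = 1.0 / (KB * T)
    series = [w.production for w in windows]
    if grid is None:
        lo = min(s.min() for s in series)
        hi = max(s.max() for s in series)
        grid = np.arange(lo - bin_width, hi + 2 * bin_width, bin_width)
    edges = np.asarray(grid, dtype=float)
    x = 0.5 * (edges[:-1] + edges[1:])
    n_ib = np.stack(
        [np.histogram(s, bins=edges)[0].astype(float) for s in series]
    )
    _warn_on_poor_overlap(windows, n_ib, min_overlap)
    N_i = n_ib.sum(axis=1)
    # bias energies on the grid
    U_ib = np.stack(
        [0.5 * w.k_u * (x - w.center) ** 2 for w in windows]
    )
    log_boltz = -beta * U_ib  # (n_windows, n_bins)
    with np.errstate(divide="ignore"):
        log_n_tot = np.log(n_ib.sum(axis=0))  # -inf for empty bins
    f = np.zeros(len(windows))  # f_i in units of kBT
    logN = np.log(N_i)
    for it in range(max_iter):
        # log denominator per bin: logsumexp over windows
        a = logN[:, None] + f[:, None] + log_boltz
        amax = a.max(axis=0)
        log_den = amax + np.log(np.exp(a - amax).sum(axis=0))
        logP = log_n_tot - log_den
        # update f_i = -ln sum_b P_b exp(-beta U_ib)
        b = logP[None, :] + log_boltz
        bmax = b.max(axis=1)
        new_f = -(bmax + np.log(np.exp(b - bmax[:, None]).sum(axis=1)))
        new_f -= new_f[0]
        resid = np.abs(new_f - f).max()
        f = new_f
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} kBT)"
        )
    F = np.where(np.isfinite(logP), -logP / beta, np.inf)
    support = n_ib.sum(axis=0)
    F = np.where(support > 0, F, np.nan)
    F -= np.nanmin(F)
    return FreeEnergyProfile(x=x, F=F, support=support, n_iterations=it + 1)


def _warn_on_poor_overlap(
    windows: list[UmbrellaWindow], n_ib: np.ndarray, min_overlap: int
) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        shared = np.minimum(n_ib[a], n_ib[b]).sum()
        if shared < min_overlap:
            import warnings

            warnings.warn(
                f"windows at {windows[a].center:.2f} and "
                f"{windows[b].center:.2f} nm share only {shared:.0f} counts",
                stacklevel=3,
            )


@dataclass
class SensingForce:
    """Buffer-zone mean force on the probe, in both unit systems."""

    slope_kj_mol_nm: float  # positive = attraction toward the thin zone
    slope_se: float
    force_pn: float
    n_points: int


def sensing_force(
    profile: FreeEnergyProfile, geom: ZoneGeometry
) -> SensingForce:
    """OLS slope of F over the buffer-zone grid points.

    The fit runs on the coordinate "outward distance from the thin-zone
    center", so a profile that climbs away from the thin zone gives a
    positive slope = attraction toward the thin zone.
    """
    delta = np.abs(np.mod(profile.x, geom.X_box) - geom.x_c)
    m = (
        (delta > geom.thin_half)
        & (delta < geom.buffer_edge)
        & (profile.support > 0)
        & np.isfinite(profile.F)
    )
    if m.sum() < 5:
        raise ValueError(
            f"only {int(m.sum())} buffer-zone grid points with support (< 5)"
        )
    xi, y = delta[m], profile.F[m]
    A = np.column_stack([xi, np.ones_like(xi)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    dof = xi.size - 2
    if dof > 0 and res.size:
        s2 = float(res[0]) / dof
        se = float(np.sqrt(s2 / np.sum((xi - xi.mean()) ** 2)))
    else:
        se = 0.0
    return SensingForce(
        slope_kj_mol_nm=slope,
        slope_se=se,
        force_pn=convert_force(slope),
        n_points=int(m.sum()),
    )


def convert_force(f: float) -> float:
    """kJ mol^-1 nm^-1 -> pN (1 kJ/mol/nm = 1.6605 pN)."""
    return kj_per_mol_nm_to_pn(f)


def to_kbt(F: float, T: float) -> float:
    """Energy in kJ/mol -> multiples of kBT at temperature T."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return F / (KB * T)


def reparameterize_thickness(
    profile: FreeEnergyProfile,
    fit: SigmoidFit,
    geom: ZoneGeometry,
    T: float = 310.0,
    jacobian_correction: bool = False,
    n_points: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-express F(x) as a function of local membrane thickness F(a).

    Uses the closed-form inverse of the sigmoid thickness profile,
    xi(a) = x0 - ln(L / (a - b) - 1) / kappa, on a thickness grid spanning
    the open interval (b + L, b) clipped to the buffer zone.  With
    ``jacobian_correction`` the density term -kBT ln|dxi/da| is added
    (probability reweighting under the change of variable); the default
    is the plain pullback, which preserves endpoint free-energy
    differences.  Requires a strictly monotone fit (kappa * L != 0).
    """
    if fit.degenerate or fit.kappa == 0.0 or fit.L == 0.0:
        raise ValueError("sigmoid fit is not strictly monotone")
    # parameterize by the buffer coordinate xi: the sigmoid can saturate
    # within the buffer (steep kappa), which makes an a-spaced grid
    # degenerate, while a(xi) on a uniform xi grid spans exactly the
    # thickness values attained inside the buffer zone
    xi = np.linspace(0.0, geom.A_buffer, n_points)
    a = np.asarray(fit(xi), dtype=float)
    # map buffer coordinate xi back to box coordinate on the profile's side
    delta = np.abs(np.mod(profile.x, geom.X_box) - geom.x_c)
    m = (profile.support > 0) & np.isfinite(profile.F)
    left = np.sum(m & (profile.x < geom.x_c))
    right = np.sum(m & (profile.x >= geom.x_c))
    side = -1.0 if left >= right else 1.0
    x_box = geom.x_c + side * (geom.thin_half + xi)
    F_a = np.interp(x_box, profile.x[m], profile.F[m])
    if jacobian_correction:
        u = a - fit.b
        # keep u off the exact asymptote where the map's slope diverges
        u = np.where(np.abs(u) < 1e-12, -1e-12 * np.sign(fit.L), u)
        dxi_da = fit.L / (fit.kappa * u * (fit.L - u))
        F_a = F_a - KB * T * np.log(np.abs(dxi_da))
    F_a = F_a - np.nanmin(F_a)
    order = np.argsort(a)
    return a[order], F_a[order]
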