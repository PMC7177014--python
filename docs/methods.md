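# Methods

`memthin` implements a protocol for inducing and quantifying lipid
packing defects in flat bilayers: a zone-scaled harmonic *squeeze field*
locally thins the membrane, and an analysis pipeline measures the
consequences — the thickness profile and its sigmoid shape, the
statistics of solvent-exposed tail patches, composition sorting along
the thinning gradient, and the thermodynamic force that pulls
amphipathic molecules toward the defect-rich region.

## The thinning field

The box is split along x into a centered **thin zone** of length
`A_thin`, two flanking **buffer zones** of length `A_buffer`, and the
remaining **normal zone**, contiguous across the periodic boundary.
Every lipid *tail* bead farther than `D/2` from the bilayer midplane
feels a harmonic force toward the midplane,

    F_z = d · C(x) · k · (D/2 − |z|),

where `d = ±1` selects the inward direction (0 inside the slab
`|z| ≤ D/2`), and `C(x)` ramps linearly from 1 in the thin zone to 0 at
the buffer/normal boundary.  `D` sets the minimal membrane thickness the
field drives toward; `k` (kJ mol⁻¹ nm⁻²) sets its stiffness.  Reference
defaults are `k = 20`, `D = 1 nm`, `A_thin = A_buffer = 10 nm` on a
55 nm box.

Two properties deserve emphasis:

* **The field is not conservative.**  `F_z` depends on x through `C(x)`
  but has no x-component, so it is not the gradient of any potential.
  It is applied as a bare force, excluded from the reported potential
  energy and the virial; the Langevin thermostat absorbs the small net
  work it performs.  This mirrors force-based external-field
  implementations in standard MD engines.
* **The midplane is recomputed every step** as the mean z of all lipid
  beads, which removes slow drift without a center-of-mass removal
  scheme.  For a non-drifting membrane this coincides with a fixed
  midplane.

## The surrogate membrane model

The internal force field is a Cooke/Deserno-class implicit-solvent
model: each lipid is one head bead plus a chain of tail beads (three
beads per chain, 1 + 2, by default).  All beads repel through a WCA core
(tail σ = 0.5 nm, head σ = 0.475 nm for single-chain species), tail
beads of different molecules attract through a smoothly truncated cos²
well of depth ε and width w_c = 0.8 nm = 1.6 σ, chains are held together
by stiff harmonic bonds (k = 800 kJ mol⁻¹ nm⁻²) and straightened by a
cosine bending term `k_bend (1 + cos θ)`.  At 310 K the baseline
ε = 2.34 kJ/mol gives kT/ε ≈ 1.10, inside the model's fluid-bilayer
window.  The cos² well is evaluated with degree-9/10 Taylor polynomials
(|error| < 3 × 10⁻⁶) for speed; forces remain consistent with the
energy to the same accuracy.

During development the two-chain variants (two chains sharing one head)
were scanned extensively — head diameters 0.475–0.70 nm, tail ε
1.8–2.8 kJ/mol, areas per lipid 0.40–0.68 nm², with and without
inter-chain rung bonds — and never produced a tensionless, fluid,
leaflet-stable bilayer: they either carry > 30 mN/m residual tension or
lose leaflet integrity.  All default species are therefore
single-chain; a two-chain topology remains available through
`LipidSpecies(n_chains=2)`.

Species surrogates express the physical feature that drives their
sorting behavior:

| species | knob                                         | intent |
|---------|----------------------------------------------|--------|
| POPC    | baseline (ε = 2.34, bend 23, 2 tail beads)   | reference membrane former |
| POPE    | head–head attraction 3.0 kJ/mol, head σ 0.44 | hydrogen-bonding, small PE headgroup |
| CHOL    | 3 tail beads, bend 80, ε 2.6                 | long stiff ordering sterol |
| LYPC    | 1 tail bead                                  | halved tail volume (lyso-lipid) |
| PLPC    | ε 1.95, bend 3                               | weakly hydrophobic, disordered tails |

The baseline bilayer is tensionless at an area per lipid of 0.255 nm²
(measured via the virial lateral tension; the builder's default), is
fluid (lateral D ≈ 2.5 × 10⁻³ nm²/ps), and has a head-to-head thickness
of ≈ 2.2 nm.  Bead mass (18 amu) and friction (0.3 ps⁻¹) are free
coarse-graining choices set to maximize lipid diffusion per integration
step; dt = 0.01 ps is stable with a wide margin (NVE drift < 0.1% over
10⁴ steps).

## Dynamics

BAOAB Langevin splitting with the exact Ornstein–Uhlenbeck velocity
update; an implicit-solvent membrane has no momentum-conserving medium,
so a stochastic thermostat is the physically appropriate choice (the
original protocol's velocity-rescaling thermostat assumes explicit
solvent).  Nonbonded interactions run over a Verlet list built from a
linked-cell grid (skin 0.3 nm, displacement-triggered rebuilds); forces
are continuous at all cutoffs.  The ensemble is fixed-box: instead of a
semi-isotropic barostat, the builder's area per lipid is calibrated once
so the field-free membrane is tensionless — the stated goal of the
original pressure-coupling procedure — and `measure_lateral_tension`
exposes the virial tension γ = L_z (P_zz − (P_xx + P_yy)/2) with a
block-averaged error for re-calibration after model changes.

## Analyses

**Thickness.** Per x-bin and frame, thickness is the mean z of
upper-leaflet head beads minus that of lower-leaflet head beads (a
per-bin leaflet-surface estimator; nearest-neighbor pairing is noisier
at desk-scale lipid counts).  Default bin width is X_box/110 (≈ 0.5 nm
at reference size).  Profiles can be symmetrized about the thin-zone
center (plain two-sided mean).  The buffer-zone profile is fitted with
the logistic sigmoid `a(ξ) = L/(1 + e^(−κ(ξ−x0))) + b` in the outward
coordinate ξ measured from the thin-zone edge; with this convention the
reference parameter set (L = −1.22 nm, κ = −19.14 nm⁻¹, x0 = 1.11 nm,
b = 4.08 nm) rises from the thin plateau b + L to the baseline b.  The
fit tries both κ signs and reports the L ≤ 0 branch; a flat profile is
flagged degenerate rather than fitted.

**Packing defects.**  A zone of the membrane is rasterized onto a
1 Å xy-grid; each cell is scanned from the solvent side toward the
midplane, and it is a defect cell iff the first bead whose xy-projected
disk covers it is a tail bead (or nothing covers it at all).  Coverage
radii are van der Waals radii (half the 2^{1/6} σ potential minimum).
4-connected defect cells are clustered (periodic in y); thin- and
normal-zone statistics are collected over *equal-width* windows because
clusters truncate at window edges.  The defect-area distribution's
exponential tail `p(A) ∝ exp(−A/π_c)` is fitted as the negative inverse
slope of a count-weighted linear fit of ln p(A), restricted to
A ≥ 15 Å² and empirical p(A) ≥ 10⁻⁴.  The reported constant is the
pooled fit; blocks give the standard error only, with the fit range
frozen from the pooled histogram — numerical experiments show per-block
fits at n = 4000 carry a +8–10% zero-truncation bias while the pooled
fit is unbiased to < 1%.

**Sorting.**  Lipid position is the head-bead x (consistent with the
thickness analysis).  Composition histograms use 50 bins by default and
pool frames (and replicas) before normalization.  Zone enrichment is
the zone's species mole fraction divided by the initial fraction; bins
straddling a zone boundary contribute in proportion to overlap length,
and buffer bins are excluded from the thin/normal numbers (reported
separately on request).

**Umbrella sampling + WHAM.**  A rigid two-row amphipathic probe
(hydrophobic row facing the membrane, polar row facing solvent; a
generic surrogate for helical lipid-packing sensors) is restrained by a
harmonic umbrella on its mass-weighted COM x-coordinate.  Windows are
seeded sequentially — each starts from the previous window's end state,
the discrete analogue of cutting frames from a continuous pull — which
removes the bistability of placing a fresh probe at every center.
Standard self-consistent WHAM (tolerance 10⁻⁷ kT on window free
energies, 0.05 nm default bins, log-sum-exp stabilized) yields F(x),
min-anchored at zero.  The sensing force is the OLS slope of F over the
buffer-zone grid points in the coordinate "outward distance from the
thin-zone center", so positive slope = attraction toward the thin zone;
it is reported in kJ mol⁻¹ nm⁻¹ and pN (1 kJ mol⁻¹ nm⁻¹ =
1.6605 pN, CODATA 2018 constants).  `reparameterize_thickness` maps
F(x) to F(a) through the sigmoid inverse, parameterized on a uniform
buffer-coordinate grid because a steep sigmoid saturates within the
buffer (an a-spaced grid would degenerate).  Whether the thickness
density correction −kT ln|dx/da| belongs in F(a) is convention-
dependent; both the plain pullback (default, preserves endpoint
differences) and the corrected transform (`jacobian_correction=True`)
are implemented, and neither is claimed as canonical.

## Desk-scale protocol and what it shows

The reference system (55 × 10 nm², ~4 nm MARTINI bilayer, μs sampling)
is beyond a single CPU core.  `memthin.protocols` therefore fixes a
*desk-scale* study: the same zone proportions on a 12 × 3.6 nm box
(~1000–1700 beads), D scaled to the surrogate thickness (0.6 nm against
2.2 nm as 1 nm is to 4 nm), runs of 2–6 × 10⁵ fs, binary 70/15/15
sorting mixtures, and an 11-window umbrella ladder (k_u = 200
kJ mol⁻¹ nm⁻², 0.25 nm spacing) across one buffer zone.  At this scale
the package's simulation claims are *sign and ordering properties*:
thin-zone thinning that grows with k, a larger defect size constant in
the thin zone, enrichment of single-tail/disordered surrogates and
depletion of PE/sterol surrogates, and a positive defect-sensing force
on the probe.  The reference system's magnitudes (4.03/2.85 nm
thicknesses, 20.62/16.28 Å² constants, 6.89 kJ mol⁻¹ nm⁻¹) are not
reproduced by the surrogate and are used only as generator truths for
estimator-recovery studies and unit-conversion arithmetic.

## Known limitations

* The surrogate has no explicit solvent, electrostatics, or chemical
  specificity; species differences are single-knob caricatures.  In
  particular the sterol surrogate's depletion from the thin zone is
  weak: the squeeze field acts on tail positions directly and a stiff
  rod can evade it by tilting, so the modulus-mediated mechanism that
  drives real cholesterol thermodynamics has no strong counterpart
  here, and the sterol sorting direction is not reliably resolved at
  desk scale.
* Thinning in a fixed box is opposed by the area constraint (the thin
  zone can only expand area that the rest of the box gives up), so the
  relative thickness change at k = 20 is ~5%, not the ~30% of the
  pressure-coupled reference setup.
* Leaflet assignment is static from the build; rare lipid flip-flops
  are not re-assigned.
* Synthetic fixtures model ideal noise (Gaussian thickness jitter,
  exactly exponential defect areas, Boltzmann-exact umbrella samples);
  passing recovery tests demonstrates estimator correctness, not
  robustness to correlated MD noise.
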