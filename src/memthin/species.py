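"""Coarse-grained lipid species definitions for the implicit-solvent model.

Each lipid is a head bead plus one or two chains of tail beads (three per
chain by default), in the spirit of minimal implicit-solvent bilayer
models: all beads repel through a WCA core, tail beads of different
molecules attract through a smoothly truncated cos^2 well, and chains are
kept straight by harmonic bonds plus a cosine bending term.

The registered species are *surrogates* for common phospholipids, chosen
to reproduce the qualitative feature that matters for thinning-induced
sorting rather than any chemistry-specific detail:

=========  =====================================================
POPC       baseline two-chain lipid; reference membrane former
POPE       POPC with stronger head-head attraction (models the
           hydrogen-bonding PE headgroup)
CHOL       single short stiff chain with strong tail attraction
           (rigid, membrane-ordering sterol)
LYPC       single-chain (lyso) lipid, otherwise POPC-like
PLPC       polyunsaturated surrogate: weaker tail attraction and a
           floppier chain (disorder-preferring)
=========  =====================================================
"""
from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["LipidSpecies", "default_species_table", "DEFAULT_AREA_PER_LIPID"]

#: Default area per lipid (nm^2) for the baseline species, calibrated once so
#: that a flat field-free bilayer is close to tensionless (see docs/methods.md).
DEFAULT_AREA_PER_LIPID = 0.255


@dataclass(frozen=True)
class LipidSpecies:
    """Parameters of one coarse-grained lipid species.

    Energy scales are in kJ/mol, the bending stiffness in kJ/mol (cosine
    bending potential ``k*(1+cos(theta))``, harmonic in the deflection
    angle near a straight chain).
    """

    name: str
    n_tail_beads: int = 2
    n_chains: int = 1
    head_epsilon: float = 0.0
    tail_epsilon: float = 2.34
    bend_k: float = 23.0
    #: WCA diameter of the head bead (nm).  Two-chain lipids need a head
    #: wide enough to sterically shield both chains; None picks the
    #: per-chain-count default (0.475 nm single-chain, 0.70 nm two-chain).
    head_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.n_tail_beads < 1:
            raise ValueError("n_tail_beads must be >= 1")
        if self.n_chains not in (1, 2):
            raise ValueError("n_chains must be 1 or 2")
        if min(self.head_epsilon, self.tail_epsilon, self.bend_k) < 0:
            raise ValueError("energy scales must be >= 0")
        if self.head_sigma is None:
            object.__setattr__(
                self, "head_sigma", 0.475 if self.n_chains == 1 else 0.70
            )

    @property
    def n_beads(self) -> int:
        return 1 + self.n_chains * self.n_tail_beads


def default_species_table() -> dict[str, LipidSpecies]:
    """The built-in species registry (fresh copies; safe to mutate).

    All surrogates are single-chain three-bead lipids (both acyl chains
    of a glycerophospholipid are coarse-grained into one CG chain; see
    docs/methods.md).  Species differ in the knob that captures their
    physics: POPE in head-head attraction, CHOL in chain stiffness and
    cohesion, LysoPC in tail volume, PLiPC in tail cohesion and
    flexibility.
    """
    popc = LipidSpecies("POPC")
    return {
        "POPC": popc,
        "POPE": replace(popc, name="POPE", head_epsilon=3.0, head_sigma=0.44),
        "CHOL": replace(popc, name="CHOL", n_tail_beads=3, tail_epsilon=2.6, bend_k=80.0),
        "LYPC": replace(popc, name="LYPC", n_tail_beads=1),
        "PLPC": replace(popc, name="PLPC", tail_epsilon=1.95, bend_k=3.0),
    }
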