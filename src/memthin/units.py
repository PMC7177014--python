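"""Physical constants and unit conversions (MD units: nm, ps, kJ/mol, K, amu).

Constants are pinned to CODATA 2018 so conversions are bit-stable across runs.
"""

#: Avogadro constant, 1/mol (CODATA 2018, exact).
N_AVOGADRO = 6.02214076e23

#: Molar gas constant, kJ mol^-1 K^-1 (CODATA 2018, exact).
R_GAS = 8.31446261815324e-3

#: Boltzmann constant in MD units == R_GAS (energy is per mole).
KB = R_GAS


def kbt(T: float) -> float:
    """Thermal energy kB*T in kJ/mol at temperature ``T`` (K)."""
    return KB * T


def kj_per_mol_nm_to_pn(f: float) -> float:
    """Convert a force from kJ mol^-1 nm^-1 to piconewton.

    1 kJ/mol/nm = 1e3 J / N_A / 1e-9 m = 1e12/(N_A*1e-3) pN ~= 1.6605 pN.
    """
    return f * 1.0e3 / (N_AVOGADRO * 1.0e-21)


#: Pressure conversion: kJ mol^-1 nm^-3 -> bar.
BAR_PER_KJ_MOL_NM3 = 1.0e25 / N_AVOGADRO

#: Tension conversion: kJ mol^-1 nm^-2 -> mN/m.
MN_PER_M_PER_KJ_MOL_NM2 = 1.0e24 / N_AVOGADRO
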