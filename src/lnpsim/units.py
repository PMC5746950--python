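"""Unit system and physical constants.

Internal units follow the GROMACS convention, which closes under
Newton's equations without conversion factors:

=========  =============  =====================================
quantity   unit           note
=========  =============  =====================================
length     nm
time       ps             the 20 fs time step is 0.02 ps
mass       amu (g/mol)    every CG bead weighs 72 amu
energy     kJ/mol         1 amu nm^2/ps^2 == 1 kJ/mol exactly
velocity   nm/ps
force      kJ/mol/nm
pressure   kJ/mol/nm^3    converted to atm for reporting
=========  =============  =====================================
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.008_314_462_618

#: 1 kJ mol^-1 nm^-3 expressed in atm (1.66054e6 Pa / 101325 Pa).
KJ_PER_NM3_TO_ATM = 16.387_724

#: Mass of every Martini bead, amu.
BEAD_MASS = 72.0

#: Femtoseconds to picoseconds.
FS = 1e-3


def pressure_to_atm(p_internal: float) -> float:
    """Convert pressure from kJ/mol/nm^3 to atm."""
    return p_internal * KJ_PER_NM3_TO_ATM


def pressure_from_atm(p_atm: float) -> float:
    """Convert pressure from atm to kJ/mol/nm^3."""
    return p_atm / KJ_PER_NM3_TO_ATM
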