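"""Physical constants and unit conventions.

Units used throughout the package: lengths in Å, energies in kcal/mol,
temperatures in K, charges in elementary-charge units.  Time is measured in
the simulator's internal unit τ (one Langevin step advances 0.3 τ by
default); it is deliberately not mapped to physical seconds.
"""

#: Boltzmann constant, kcal/(mol K).
KB = 0.0019872041

#: Coulomb prefactor e^2/(4 pi eps0), kcal Å/(mol e^2).
COULOMB = 332.0637

#: Standard-state volume per molecule at 1 M, Å^3.
STANDARD_VOLUME = 1661.0

#: Vacuum permittivity, F/m (used for the Debye length).
EPS0 = 8.8541878128e-12

#: Boltzmann constant, J/K.
KB_SI = 1.380649e-23

#: Elementary charge, C.
E_CHARGE = 1.602176634e-19

#: Avogadro number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Acidic / basic residue charges used by the integer-charge scheme.
RESIDUE_CHARGES = {
    "ASP": -1.0,
    "GLU": -1.0,
    "LYS": +1.0,
    "ARG": +1.0,
}

#: Three-letter residue codes recognised by the charge assigner.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def kt(temperature: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KB * temperature
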