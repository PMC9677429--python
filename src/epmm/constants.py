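"""Physical constants and unit conversions.

Internal working units are Hartree atomic units (e, Bohr, Hartree); all
public I/O is in Angstrom and kcal/mol.  CODATA 2018 values.
"""

BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

HARTREE_TO_KCALMOL = 627.509474

#: Coulomb constant in kcal mol^-1 Angstrom e^-2, used for point-charge sums.
COULOMB_KCAL_A = HARTREE_TO_KCALMOL * BOHR_TO_ANGSTROM  # 332.06371...

ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20,
}

#: Covalent radii (Angstrom) used for bond detection (Cordero-style values).
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Na": 1.66, "Mg": 1.36, "P": 1.07, "S": 1.05, "Cl": 1.02,
    "K": 2.03, "Ca": 1.76,
}

#: Relative atomic masses, used only to pick the "heaviest neighbor" when
#: resolving atom-local frames.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078,
}


def atomic_number(element: str) -> int:
    try:
        return ATOMIC_NUMBERS[element.capitalize()]
    except KeyError:
        raise KeyError(f"element {element!r} not supported") from None
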