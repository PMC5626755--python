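"""Physical constants and element tables shared across modules."""

# Boltzmann constant in kcal/mol/K (all energies kcal/mol, temperatures K).
KB_KCAL_MOL_K = 0.0019872041

# Atomic masses, amu (standard atomic weights, rounded).
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
    "MN": 54.938,
}

# van der Waals radii (Angstrom) for SASA; probe default 1.4 A.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "H": 1.20,
}

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}

AA_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H",
}

NUCLEOTIDES = {
    "A", "C", "G", "U", "T",
    "ADE", "CYT", "GUA", "URA", "THY",
    "DA", "DC", "DG", "DT", "RA", "RC", "RG", "RU",
}

PURINES = {"A", "G", "ADE", "GUA", "DA", "DG", "RA", "RG"}
PYRIMIDINES = {"C", "U", "T", "CYT", "URA", "THY", "DC", "DT", "RC", "RU"}

# Atom-name partition of a nucleotide into its two network nodes.
BASE_ATOM_NAMES = {
    "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
    "O2", "O4", "O6", "N2", "N4", "N6", "C5M", "C7",
}
SUGAR_PHOSPHATE_ATOM_NAMES = {
    "P", "OP1", "OP2", "O1P", "O2P", "O3P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}
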