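"""Amino acid constants shared across the package.

Residue types are handled as one-letter codes internally; PDB I/O converts
to and from three-letter names.
"""

from __future__ import annotations

AA3_TO_AA1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3: dict[str, str] = {v: k for k, v in AA3_TO_AA1.items()}
STANDARD_AA1: frozenset[str] = frozenset(AA1_TO_AA3)

# Number of chi dihedrals parameterised by rotamer libraries (chi1..chi4).
CHI_COUNTS: dict[str, int] = {
    "A": 0, "G": 0,
    "C": 1, "S": 1, "T": 1, "V": 1,
    "D": 2, "F": 2, "H": 2, "I": 2, "L": 2, "N": 2, "P": 2, "W": 2, "Y": 2,
    "E": 3, "M": 3, "Q": 3,
    "K": 4, "R": 4,
}

# Heavy-atom count of the side chain (CB onward).  Drives the
# "larger/smaller" fast-path rule.
SIDECHAIN_SIZE: dict[str, int] = {
    "G": 0, "A": 1,
    "C": 2, "S": 2,
    "P": 3, "T": 3, "V": 3,
    "D": 4, "N": 4, "I": 4, "L": 4, "M": 4,
    "E": 5, "Q": 5, "K": 5,
    "H": 6,
    "F": 7, "R": 7,
    "Y": 8,
    "W": 10,
}

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

WATER_NAMES: frozenset[str] = frozenset({"HOH", "WAT", "DOD"})

def is_sidechain_atom(name: str) -> bool:
    return name not in BACKBONE_ATOMS
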