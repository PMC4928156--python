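"""Per-amino-acid scales and constants used across the package.

All tables are keyed by one-letter amino-acid code and cover exactly the 20
standard residues.  Each scale is pluggable at the call sites that use it;
the values packaged here are the documented defaults:

* ``KD_HYDROPATHY`` — Kyte–Doolittle hydropathy scale.
* ``DAYHOFF_MUTABILITY`` — Dayhoff-style relative mutability (Ala = 100).
* ``MOLECULAR_WEIGHT`` — average isotopic mass of the free amino acid, Da.
* ``MAX_ACC`` — Rost & Sander-style theoretical maximum solvent-accessible
  area per residue type, Å², used to normalise SASA into RSA.
* ``VDW_RADII`` — Chothia-style van-der-Waals radii by element, Å, used by
  the Shrake–Rupley surface calculation (hydrogens are never assigned a
  radius: they are excluded from the heavy-atom set).
"""

from __future__ import annotations

AA1 = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA = frozenset(AA1)

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}

KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DAYHOFF_MUTABILITY = {
    "A": 100, "R": 65, "N": 134, "D": 106, "C": 20,
    "Q": 93, "E": 102, "G": 49, "H": 66, "I": 96,
    "L": 40, "K": 56, "M": 94, "F": 41, "P": 56,
    "S": 120, "T": 97, "W": 18, "Y": 41, "V": 74,
}

# Free amino acid (residue + H2O), average isotopic masses.
MOLECULAR_WEIGHT = {
    "G": 75.07, "A": 89.09, "S": 105.09, "P": 115.13, "V": 117.15,
    "T": 119.12, "C": 121.16, "L": 131.17, "I": 131.17, "N": 132.12,
    "D": 133.10, "Q": 146.15, "K": 146.19, "E": 147.13, "M": 149.21,
    "H": 155.15, "F": 165.19, "R": 174.20, "Y": 181.19, "W": 204.23,
}

MAX_ACC = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

VDW_RADII = {
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
}
VDW_DEFAULT_RADIUS = 1.80


def check_standard(aa: str) -> str:
    """Validate a one-letter code against the 20 standard residues."""
    if aa not in STANDARD_AA:
        raise ValueError(f"not a standard amino acid: {aa!r}")
    return aa
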