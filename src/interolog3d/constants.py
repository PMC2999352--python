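"""Shared amino-acid tables and background frequencies.

The 20 standard residues are indexed in the fixed alphabetical one-letter
order :data:`AA_ALPHABET`; every 20x20 matrix in the package uses that order.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order for all 20x20 matrices and profile columns.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ALPHABET)}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Chemically modified residues mapped back to their standard parent.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine scored as Cys
    "CSO": "CYS",
    "HYP": "PRO",
    "PTR": "TYR",
    "SEP": "SER",
    "TPO": "THR",
    "MLY": "LYS",
}

#: Backbone heavy-atom names; every other heavy atom is sidechain (CB included).
BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

#: Robinson & Robinson amino-acid background frequencies (normalised below).
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

BACKGROUND_FREQS: np.ndarray = np.array([_RR[a] for a in AA_ALPHABET])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: Seven physicochemical groups partitioning the 20 residues.
RESIDUE_GROUPS: dict[str, frozenset[str]] = {
    "polar_positive": frozenset("HRK"),
    "polar_negative": frozenset("DE"),
    "polar_neutral": frozenset("STNQ"),
    "cysteine": frozenset("C"),
    "nonpolar_aliphatic": frozenset("AVLIM"),
    "nonpolar_aromatic": frozenset("FYW"),
    "others": frozenset("GP"),
}

#: Sidechain nitrogen atoms carrying positive charge (salt-bridge donors).
CHARGED_N_ATOMS: dict[str, frozenset[str]] = {
    "R": frozenset({"NE", "NH1", "NH2"}),
    "K": frozenset({"NZ"}),
    "H": frozenset({"ND1", "NE2"}),
}

#: Sidechain oxygen atoms carrying negative charge (salt-bridge acceptors).
CHARGED_O_ATOMS: dict[str, frozenset[str]] = {
    "D": frozenset({"OD1", "OD2"}),
    "E": frozenset({"OE1", "OE2"}),
}
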