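"""Substitution matrices and structural reference tables.

Substitution matrices are served as dense 20x20 numpy arrays in the
package-wide residue order (see :mod:`coevonet.alignment`).  McLachlan and
BLOSUM62 come from Biopython's bundled tables; ``identity`` is 1 on the
diagonal, 0 elsewhere.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .alignment import AMINO_ACIDS

#: van der Waals radii (Angstrom) used for solvent accessibility
ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.80

#: maximum accessible surface area (A^2) per residue type in an extended
#: Gly-X-Gly tripeptide (Tien et al. 2013, theoretical values)
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: side-chain hydrogen-bond donor heavy atoms per residue type
SIDECHAIN_DONORS = {
    "R": ("NE", "NH1", "NH2"), "N": ("ND2",), "Q": ("NE2",),
    "H": ("ND1", "NE2"), "K": ("NZ",), "S": ("OG",), "T": ("OG1",),
    "W": ("NE1",), "Y": ("OH",), "C": ("SG",),
}

#: side-chain hydrogen-bond acceptor heavy atoms per residue type
SIDECHAIN_ACCEPTORS = {
    "N": ("OD1",), "D": ("OD1", "OD2"), "Q": ("OE1",),
    "E": ("OE1", "OE2"), "H": ("ND1", "NE2"), "S": ("OG",),
    "T": ("OG1",), "Y": ("OH",), "M": ("SD",),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


@lru_cache(maxsize=None)
def similarity_matrix(name: str = "mclachlan") -> np.ndarray:
    """Return a 20x20 similarity matrix in package residue order.

    ``name`` is one of ``mclachlan``, ``blosum62`` or ``identity``.
    """
    name = name.lower()
    if name == "identity":
        return np.eye(20)
    source = {"mclachlan": "MCLACHLAN", "blosum62": "BLOSUM62"}.get(name)
    if source is None:
        raise ValueError(f"unknown similarity matrix {name!r}")
    table = substitution_matrices.load(source)
    m = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            m[i, j] = table[a, b]
    m = 0.5 * (m + m.T)  # guard against asymmetric source tables
    m.setflags(write=False)
    return m
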