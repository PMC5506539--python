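"""Backbone hydrogen bonds and 3-class secondary structure.

Backbone H-bonds use the Kabsch-Sander electrostatic model
``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` (kcal/mol) with a
bond called below -0.5 kcal/mol; amide hydrogens are reconstructed along
the bisector of the C(i-1)->N and CA->N directions (1.01 A), since PDB
files usually lack them.  Helices follow the DSSP 4-turn rule (two
consecutive i -> i+4 bonds), strands the DSSP parallel/antiparallel bridge
patterns, everything else is coil.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .matrices import SIDECHAIN_ACCEPTORS, SIDECHAIN_DONORS
from .structure import StructureModel

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
KS_CONSTANT = 0.084 * 332.0
SIDECHAIN_DISTANCE_CUTOFF = 3.5  # A, donor heavy atom to acceptor heavy atom
CHAIN_BREAK_CA = 4.5  # A between consecutive CA atoms


def amide_hydrogen(s: StructureModel, i: int) -> Optional[np.ndarray]:
    """Reconstructed backbone H of residue i (None for PRO or chain start)."""
    res = s.residues[i]
    if res.name3 == "PRO" or i == 0:
        return None
    n = res.coord("N")
    ca = res.coord("CA")
    c_prev = s.residues[i - 1].coord("C")
    if n is None or ca is None or c_prev is None:
        return None
    if np.linalg.norm(n - c_prev) > 2.0:  # not covalently bonded (chain break)
        return None
    d1 = n - c_prev
    d2 = n - ca
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    bis = d1 + d2
    norm = np.linalg.norm(bis)
    if norm < 1e-6:
        return None
    return n + 1.01 * bis / norm


def backbone_hbond_energy(
    s: StructureModel, donor: int, acceptor: int
) -> Optional[float]:
    """Kabsch-Sander energy for N-H(donor) ... O=C(acceptor); None if atoms
    are missing."""
    h = amide_hydrogen(s, donor)
    n = s.residues[donor].coord("N")
    o = s.residues[acceptor].coord("O")
    c = s.residues[acceptor].coord("C")
    if h is None or n is None or o is None or c is None:
        return None
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # atom clash, call it no bond
        return 0.0
    return float(KS_CONSTANT * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn))


def _chain_breaks(s: StructureModel) -> np.ndarray:
    """break[i] True when residues i and i+1 are not covalently continuous."""
    n = len(s.residues)
    breaks = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        ca1 = s.residues[i].coord("CA")
        ca2 = s.residues[i + 1].coord("CA")
        breaks[i] = (
            ca1 is None or ca2 is None
            or np.linalg.norm(ca1 - ca2) > CHAIN_BREAK_CA
        )
    return breaks


def _contiguous(breaks: np.ndarray, i: int, j: int) -> bool:
    lo, hi = min(i, j), max(i, j)
    return not breaks[lo:hi].any()


@dataclass
class HydrogenBondReport:
    backbone: np.ndarray  # bool (n, n): donor i -> acceptor j
    sidechain: list[tuple[int, int]]  # (donor residue, acceptor residue)
    hbonded: np.ndarray  # bool per residue: participates in any bond


def detect_hydrogen_bonds(s: StructureModel) -> HydrogenBondReport:
    """All backbone and side-chain hydrogen bonds in the model."""
    n = len(s.residues)
    backbone = np.zeros((n, n), dtype=bool)
    cas = [r.coord("CA") for r in s.residues]
    for i in range(n):
        ca_i = cas[i]
        for j in range(n):
            if abs(i - j) < 2:
                continue
            if ca_i is not None and cas[j] is not None:
                if np.linalg.norm(ca_i - cas[j]) > 9.0:  # DSSP speed cutoff
                    continue
            e = backbone_hbond_energy(s, i, j)
            if e is not None and e < HBOND_ENERGY_CUTOFF:
                backbone[i, j] = True

    sidechain: list[tuple[int, int]] = []
    for i, res_i in enumerate(s.residues):
        donors = [
            res_i.atoms[a].coord
            for a in SIDECHAIN_DONORS.get(res_i.one_letter, ())
            if a in res_i.atoms
        ]
        if not donors:
            continue
        for j, res_j in enumerate(s.residues):
            if i == j:
                continue
            accs = [
                res_j.atoms[a].coord
                for a in SIDECHAIN_ACCEPTORS.get(res_j.one_letter, ())
                if a in res_j.atoms
            ]
            if not accs:
                continue
            if cdist(np.array(donors), np.array(accs)).min() <= SIDECHAIN_DISTANCE_CUTOFF:
                sidechain.append((i, j))

    hbonded = backbone.any(axis=0) | backbone.any(axis=1)
    for i, j in sidechain:
        hbonded[i] = hbonded[j] = True
    return HydrogenBondReport(backbone, sidechain, hbonded)


def assign_secondary_structure(
    s: StructureModel, bonds: Optional[HydrogenBondReport] = None
) -> np.ndarray:
    """Per-residue class in {'helix', 'strand', 'coil'}.

    A 4-turn exists at i when the N-H of residue i+4 donates to the C=O of
    residue i; two consecutive 4-turns mark residues i..i+3 as helix.
    Bridges follow the DSSP definitions; any bridge residue not already in
    a helix is a strand.  Chain breaks bound both patterns.
    """
    n = len(s.residues)
    if bonds is None:
        bonds = detect_hydrogen_bonds(s)
    hb = bonds.backbone  # hb[d, a]: donor d -> acceptor a
    breaks = _chain_breaks(s)

    def bonded(acceptor: int, donor: int) -> bool:
        # Kabsch-Sander Hbond(i, j): C=O of i accepts from N-H of j
        return (
            0 <= acceptor < n and 0 <= donor < n and hb[donor, acceptor]
        )

    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        turn4[i] = bonded(i, i + 4) and _contiguous(breaks, i, i + 4)

    ss = np.array(["coil"] * n, dtype=object)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            ss[i:i + 4] = "helix"

    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            parallel = (bonded(i - 1, j) and bonded(j, i + 1)) or (
                bonded(j - 1, i) and bonded(i, j + 1)
            )
            antiparallel = (bonded(i, j) and bonded(j, i)) or (
                bonded(i - 1, j + 1) and bonded(j - 1, i + 1)
            )
            if parallel or antiparallel:
                for k in (i, j):
                    if ss[k] == "coil":
                        ss[k] = "strand"
    return ss


@dataclass
class EnvironmentAnnotation:
    """Per-residue structural environment of the representative chain."""

    relative_accessibility: np.ndarray
    buried: np.ndarray
    ss_class: np.ndarray
    hbonded: np.ndarray

    def state(self, ridx: int) -> str:
        return "buried" if self.buried[ridx] else "accessible"


def write_environment_tsv(
    env: EnvironmentAnnotation, s: StructureModel, path
) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tname\trel_acc\tstate\tss\thbonded\n")
        for k, res in enumerate(s.residues):
            rel = env.relative_accessibility[k]
            rel_s = "" if np.isnan(rel) else f"{rel:.3f}"
            state = "" if np.isnan(rel) else env.state(k)
            fh.write(
                f"{res.number}\t{res.name3}\t{rel_s}\t{state}\t"
                f"{env.ss_class[k]}\t{int(env.hbonded[k])}\n"
            )


def annotate_environment(s: StructureModel) -> EnvironmentAnnotation:
    """SASA burial state, secondary structure and H-bond flag per residue."""
    from .sasa import shrake_rupley_accessibility

    acc = shrake_rupley_accessibility(s)
    bonds = detect_hydrogen_bonds(s)
    ss = assign_secondary_structure(s, bonds)
    return EnvironmentAnnotation(acc.relative, acc.buried, ss, bonds.hbonded)
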