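"""Idealised backbone construction from internal coordinates.

Builds poly-alanine-like backbones (N, CA, C, O atoms) from phi/psi torsion
lists using standard bond lengths and angles, via sequential placement
(the natural-extension reference frame).  Used for secondary-structure and
solvent-accessibility fixtures and by the synthetic structure generator.
"""

from __future__ import annotations

import numpy as np

from .structure import Atom, Residue, StructureModel

# standard backbone geometry (Engh & Huber averages)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
OMEGA = 180.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position a new atom at given internal coordinates w.r.t. a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]], residue_name: str = "ALA"
) -> StructureModel:
    """Backbone (N, CA, C, O) for the given (phi, psi) sequence."""
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    coords: list[dict[str, np.ndarray]] = []
    # seed the first residue in a canonical frame
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = N0 + np.array([B_N_CA, 0.0, 0.0])
    # dummy reference point fixes the (arbitrary) orientation of residue 1
    C0 = place_atom(
        N0 + np.array([0.0, 1.0, 0.0]), N0, CA0, B_CA_C, A_N_CA_C, 60.0
    )
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n_res):
        phi_prev, psi_prev = phi_psi[i - 1]
        prev = coords[i - 1]
        N = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, psi_prev)
        CA = place_atom(prev["CA"], prev["C"], N, B_N_CA, A_C_N_CA, OMEGA)
        phi_i = phi_psi[i][0]
        C = place_atom(prev["C"], N, CA, B_CA_C, A_N_CA_C, phi_i)
        coords.append({"N": N, "CA": CA, "C": C})
    # carbonyl oxygens: O of residue i lies opposite N(i+1) in the peptide plane
    for i in range(n_res):
        psi_i = phi_psi[i][1]
        d = coords[i]
        d["O"] = place_atom(d["N"], d["CA"], d["C"], B_C_O, A_CA_C_O, psi_i + 180.0)
    residues = [
        Residue(
            number=i + 1,
            icode="",
            name3=residue_name,
            atoms={
                name: Atom(name, name[0], xyz) for name, xyz in d.items()
            },
        )
        for i, d in enumerate(coords)
    ]
    return StructureModel("A", residues)


def ideal_helix(n_res: int) -> StructureModel:
    """Idealised alpha helix (phi = -57, psi = -47)."""
    return build_backbone([(-57.0, -47.0)] * n_res)


def ideal_strand(n_res: int) -> StructureModel:
    """Single extended beta strand (phi = -139, psi = 135)."""
    return build_backbone([(-139.0, 135.0)] * n_res)


#: rigid placement of the second strand in the two-stranded antiparallel
#: sheet fixture (rotation vector + translation), found by minimising the
#: Kabsch-Sander energies of the target inter-strand bonds for n = 6
_SHEET_ROTVEC = np.array([6.1775, -0.3433, 0.8482])
_SHEET_SHIFT = np.array([-1.9377, 2.9170, 0.1785])


def ideal_antiparallel_sheet(n_per_strand: int = 6) -> StructureModel:
    """Two-stranded idealised antiparallel beta sheet (one model, with a
    chain break between the strands)."""
    from scipy.spatial.transform import Rotation

    s1 = ideal_strand(n_per_strand)
    rot = Rotation.from_rotvec(_SHEET_ROTVEC).as_matrix()
    s2 = transform(ideal_strand(n_per_strand), rot, _SHEET_SHIFT)
    return concatenate([s1, s2])


def transform(s: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Rigid-body transformed copy of a structure."""
    residues = []
    for res in s.residues:
        atoms = {
            name: Atom(a.name, a.element, rotation @ a.coord + translation)
            for name, a in res.atoms.items()
        }
        residues.append(Residue(res.number, res.icode, res.name3, atoms))
    return StructureModel(s.chain_id, residues)


def concatenate(parts: list[StructureModel], renumber: bool = True) -> StructureModel:
    """Join several chains into one model (numbering made consecutive)."""
    residues = []
    num = 1
    for part in parts:
        for res in part.residues:
            atoms = {n: Atom(a.name, a.element, a.coord.copy())
                     for n, a in res.atoms.items()}
            residues.append(
                Residue(num if renumber else res.number, res.icode, res.name3, atoms)
            )
            num += 1
    return StructureModel(parts[0].chain_id, residues)
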