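"""Shrake-Rupley solvent accessible surface area and burial state.

Each heavy atom's sphere of radius r + probe is sampled with a
deterministic quasi-uniform (golden spiral) point set; the accessible
fraction is the share of points inside no neighbouring sphere.  Residue
ASA is the sum over its heavy atoms, and relative accessibility divides by
the residue type's maximum ASA in an extended Gly-X-Gly reference.
Residues with relative accessibility < 7% are classed as buried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
from scipy.spatial import cKDTree

from .matrices import ATOM_RADII, DEFAULT_RADIUS, MAX_ASA
from .structure import StructureModel

BURIAL_THRESHOLD = 0.07


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral construction)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


@dataclass
class AccessibilityResult:
    atom_asa: list[dict[str, float]]  # per residue: atom name -> ASA
    residue_asa: np.ndarray
    relative: np.ndarray  # NaN where no reference value exists
    buried: np.ndarray  # bool; accessible where False


def shrake_rupley_accessibility(
    s: StructureModel, probe: float = 1.4, points: int = 960
) -> AccessibilityResult:
    """Per-atom, per-residue absolute and relative solvent accessibility."""
    unit = sphere_points(points)
    coords, radii, owner, names = [], [], [], []
    for ridx, res in enumerate(s.residues):
        for atom in res.atoms.values():
            if atom.element == "H":
                continue
            r = ATOM_RADII.get(atom.element)
            if r is None:
                warnings.warn(
                    f"unknown element {atom.element!r}; using radius "
                    f"{DEFAULT_RADIUS} A"
                )
                r = DEFAULT_RADIUS
            coords.append(atom.coord)
            radii.append(r)
            owner.append(ridx)
            names.append(atom.name)
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    n_atoms = len(coords)
    tree = cKDTree(coords)
    rmax = radii.max() + probe

    atom_asa_flat = np.zeros(n_atoms)
    for k in range(n_atoms):
        rk = radii[k] + probe
        surf = coords[k] + rk * unit
        neigh = [
            j for j in tree.query_ball_point(coords[k], rk + rmax) if j != k
        ]
        exposed = np.ones(len(surf), dtype=bool)
        for j in neigh:
            rj = radii[j] + probe
            d2 = ((surf - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > rj * rj
        atom_asa_flat[k] = exposed.mean() * 4.0 * np.pi * rk * rk

    n_res = len(s.residues)
    residue_asa = np.zeros(n_res)
    atom_asa: list[dict[str, float]] = [dict() for _ in range(n_res)]
    for k in range(n_atoms):
        residue_asa[owner[k]] += atom_asa_flat[k]
        atom_asa[owner[k]][names[k]] = float(atom_asa_flat[k])
    relative = np.full(n_res, np.nan)
    for ridx, res in enumerate(s.residues):
        ref = MAX_ASA.get(res.one_letter)
        if ref:
            relative[ridx] = min(residue_asa[ridx] / ref, 1.0)
    with np.errstate(invalid="ignore"):
        buried = relative < BURIAL_THRESHOLD
    return AccessibilityResult(atom_asa, residue_asa, relative, buried)
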