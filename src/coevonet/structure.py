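"""Representative-structure handling.

Reads one chain of one model from a PDB file into a light-weight
:class:`StructureModel`, maps alignment columns onto its residues by global
sequence alignment, and applies the spatial proximity filter (<= 10 A by
default, inclusive) to significant column pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import BiopythonWarning
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .alignment import Alignment
from .conservation import ConservationProfile
from .matrices import THREE_TO_ONE
from .scoring import SignificantPair


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.isfinite(self.coord).all():
            raise ValueError(f"bad coordinates for atom {self.name}")


@dataclass
class Residue:
    number: int
    icode: str
    name3: str
    atoms: dict[str, Atom]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    def coord(self, atom_name: str) -> Optional[np.ndarray]:
        atom = self.atoms.get(atom_name)
        return None if atom is None else atom.coord

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for a in self.atoms.values() if a.element != "H"]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class StructureModel:
    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_structure(path, chain: str = "A", model: int = 1) -> StructureModel:
    """Load one chain of one model; HETATM/waters dropped, MSE kept as MET.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken toward altloc 'A').
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"no models in {path}")
    try:
        mdl = structure[model - 1]
    except KeyError:
        mdl = models[0]
    chains = {c.id for c in mdl}
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not in {path}; available: {sorted(chains)}"
        )
    residues: list[Residue] = []
    for res in mdl[chain]:
        hetflag, resseq, icode = res.id
        if hetflag not in (" ", "H_MSE"):
            continue  # other heteroatoms and waters
        atoms: dict[str, Atom] = {}
        for atom in res:
            if atom.is_disordered():
                children = sorted(
                    atom.disordered_get_list(),
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                )
                atom = children[0]
            element = (atom.element or atom.get_name()[0]).strip().upper()
            atoms[atom.get_name()] = Atom(atom.get_name(), element, atom.coord)
        if atoms:
            residues.append(Residue(resseq, icode.strip(), res.get_resname(), atoms))
    if not residues:
        raise ValueError(f"chain {chain!r} of {path} has no polymer residues")
    return StructureModel(chain, residues)


@dataclass
class ColumnResidueMap:
    """Collinear partial bijection between alignment columns and residues."""

    col_to_res: dict[int, int]
    coverage: float

    def __post_init__(self) -> None:
        cols = sorted(self.col_to_res)
        resi = [self.col_to_res[c] for c in cols]
        if any(b <= a for a, b in zip(resi, resi[1:])):
            raise ValueError("column->residue map must be strictly increasing")
        self.res_to_col = {r: c for c, r in self.col_to_res.items()}

    def __contains__(self, col: int) -> bool:
        return col in self.col_to_res

    def mapped_columns(self) -> list[int]:
        return sorted(self.col_to_res)


class MappingError(ValueError):
    """Representative sequence does not match the structure."""


def map_columns_to_residues(
    a: Alignment,
    representative_id: str,
    s: StructureModel,
    min_identity: float = 0.95,
) -> ColumnResidueMap:
    """Map alignment columns to structure residues through the representative.

    The ungapped representative row is globally aligned to the structure's
    one-letter sequence; aligned identical positions define the map.  An
    identity below ``min_identity`` over aligned positions signals a wrong
    alignment/structure pairing and raises :class:`MappingError`.
    """
    row = a.row_for(representative_id)
    cols = [c for c, ch in enumerate(row) if ch != "-"]
    seq_rep = "".join(row[c] for c in cols)
    seq_str = s.sequence
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_rep, seq_str)[0]
    col_to_res: dict[int, int] = {}
    matched = aligned_total = 0
    for (r0, r1), (s0, s1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            aligned_total += 1
            if seq_rep[r0 + k] == seq_str[s0 + k]:
                matched += 1
                col_to_res[cols[r0 + k]] = s0 + k
    if aligned_total == 0 or matched / aligned_total < min_identity:
        pct = 0.0 if aligned_total == 0 else matched / aligned_total
        raise MappingError(
            f"representative/structure identity {pct:.1%} below "
            f"{min_identity:.0%}: wrong pairing?"
        )
    coverage = len(col_to_res) / len(cols)
    return ColumnResidueMap(col_to_res, coverage)


def residue_distance(
    s: StructureModel, r1: int, r2: int, mode: str = "min_heavy"
) -> float:
    """Distance (A) between two residues; NaN when required atoms are absent."""
    a, b = s.residues[r1], s.residues[r2]
    if mode == "min_heavy":
        pa, pb = a.heavy_coords(), b.heavy_coords()
        if pa.size == 0 or pb.size == 0:
            return float("nan")
        return float(cdist(pa, pb).min())
    if mode in ("ca", "cb"):
        def pick(res: Residue) -> Optional[np.ndarray]:
            if mode == "cb" and res.name3 != "GLY":
                c = res.coord("CB")
                if c is not None:
                    return c
            return res.coord("CA")
        ca, cb_ = pick(a), pick(b)
        if ca is None or cb_ is None:
            return float("nan")
        return float(np.linalg.norm(ca - cb_))
    raise ValueError(f"unknown distance mode {mode!r}")


def distance_matrix(s: StructureModel, mode: str = "min_heavy") -> np.ndarray:
    """Symmetric residue-residue distance matrix (NaN where unscoreable)."""
    n = len(s.residues)
    if mode == "min_heavy":
        pts, owner = [], []
        for idx, res in enumerate(s.residues):
            hc = res.heavy_coords()
            pts.append(hc)
            owner.extend([idx] * len(hc))
        allp = np.concatenate([p for p in pts if p.size], axis=0)
        owner = np.asarray(owner)
        d = cdist(allp, allp)
        out = np.full((n, n), np.nan)
        for i in range(n):
            sel_i = owner == i
            if not sel_i.any():
                continue
            for j in range(i, n):
                sel_j = owner == j
                if not sel_j.any():
                    continue
                out[i, j] = out[j, i] = d[np.ix_(sel_i, sel_j)].min()
        return out
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = residue_distance(s, i, j, mode)
    return out


@dataclass
class SpatialFilterResult:
    kept: list[SignificantPair]
    total: int
    unmapped: int

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def spatial_filter(
    pairs: Sequence[SignificantPair],
    m: ColumnResidueMap,
    s: StructureModel,
    max_distance: float = 10.0,
    mode: str = "min_heavy",
    dmat: Optional[np.ndarray] = None,
) -> SpatialFilterResult:
    """Keep pairs whose mapped residues are within ``max_distance`` (inclusive)."""
    if dmat is None and pairs:
        dmat = distance_matrix(s, mode)
    kept, unmapped = [], 0
    for p in pairs:
        if p.i not in m or p.j not in m:
            unmapped += 1
            continue
        d = dmat[m.col_to_res[p.i], m.col_to_res[p.j]]
        if np.isfinite(d) and d <= max_distance:
            kept.append(p)
    return SpatialFilterResult(kept, len(pairs), unmapped)


def write_annotated_structure(
    s: StructureModel,
    profile: ConservationProfile,
    m: ColumnResidueMap,
    pairs: Sequence[SignificantPair],
    out_pdb,
    out_edges=None,
) -> None:
    """Write a PDB with B-factors replaced by CI, plus a CA-CA edge list.

    Mapped residues carry the CI of their column (clamped to the B-factor
    field range); unmapped residues get 0.00.
    """
    def ci_for(res_idx: int) -> float:
        col = m.res_to_col.get(res_idx)
        if col is None or profile.gap_mask[col]:
            return 0.0
        return float(np.clip(profile.ci[col], -9.99, 99.99))

    serial = 1
    with open(out_pdb, "w") as fh:
        for ridx, res in enumerate(s.residues):
            b = ci_for(ridx)
            for atom in res.atoms.values():
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.name3:>3s} "
                    f"{s.chain_id:1s}{res.number:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")

    if out_edges is not None:
        with open(out_edges, "w") as fh:
            fh.write("res_i\tres_j\tcol_i\tcol_j\tz\tmethod\n")
            for p in pairs:
                if p.i not in m or p.j not in m:
                    continue
                ri, rj = m.col_to_res[p.i], m.col_to_res[p.j]
                fh.write(
                    f"{s.residues[ri].number}\t{s.residues[rj].number}\t"
                    f"{p.i + 1}\t{p.j + 1}\t{p.z:.4g}\t{p.method}\n"
                )
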