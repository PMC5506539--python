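"""Synthetic families: Potts-model alignments with planted couplings and
idealised coordinates.

The generator emulates what the analysis assumes about real data: columns
with tunable conservation (single-site fields), sparse pairwise couplings
planted between spatially close sites (|i - j| > 6, within 10 A in the
generated coordinates), a conserved gapless core flanked by variable,
gap-bearing columns, and a representative first sequence matching the
structure.  A cohort spans a field-strength gradient with coupling density
increasing toward the variable end, and hub-biased coupling placement
concentrates couplings on a minority of strongly constrained sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .alignment import AMINO_ACIDS, Alignment, FamilyRecord
from .dca import PottsCouplings
from .geometry import ideal_helix
from .matrices import ONE_TO_THREE
from .structure import Atom, Residue, StructureModel


def sample_potts_alignment(
    L: int,
    N: int,
    params: PottsCouplings,
    sweeps: int = 100,
    seed: int = 0,
    ids: Optional[list[str]] = None,
) -> Alignment:
    """Gibbs-sample N independent sequences from a 20-state Potts model.

    P(s) is proportional to exp(sum_i h_i(s_i) + sum_{i<j} J_ij(s_i, s_j)).
    Each sequence is an independent chain run for ``sweeps`` full sweeps
    from a uniform random start (no phylogeny).  Coupling-free models are
    sampled directly from the single-site Boltzmann distributions, which
    is the exact stationary law in that case.
    """
    if params.L != L:
        raise ValueError("params.L does not match L")
    rng = np.random.default_rng(seed)
    h = params.h
    q = params.q
    partners: dict[int, list[int]] = {i: [] for i in range(L)}
    for (i, j) in params.pairs:
        partners[i].append(j)
        partners[j].append(i)

    if not params.J:
        gumb = rng.gumbel(size=(N, L, q))
        state = (h[None, :, :] + gumb).argmax(axis=2)
    else:
        state = rng.integers(0, q, size=(N, L))
        for _ in range(max(sweeps, 1)):
            for i in range(L):
                logits = np.broadcast_to(h[i], (N, q)).copy()
                for j in partners[i]:
                    logits += params.coupling(i, j)[:, state[:, j]].T
                gumb = rng.gumbel(size=(N, q))
                state[:, i] = (logits + gumb).argmax(axis=1)

    lut = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    rows = [bytes(lut[row]).decode() for row in state]
    if ids is None:
        ids = [f"seq{k}" for k in range(N)]
    return Alignment(ids=list(ids), rows=rows)


def inject_gaps(
    a: Alignment,
    columns: Sequence[int],
    rate: float,
    seed: int = 0,
    keep_rows: Sequence[int] = (0,),
) -> Alignment:
    """Replace residues by gaps in the given columns at the given per-cell
    rate; rows in ``keep_rows`` (the representative by default) stay intact."""
    rng = np.random.default_rng(seed)
    rows = [list(r) for r in a.rows]
    keep = set(keep_rows)
    for c in columns:
        hit = rng.random(a.N) < rate
        for k in np.nonzero(hit)[0]:
            if int(k) not in keep:
                rows[k][c] = "-"
    return Alignment(ids=list(a.ids), rows=["".join(r) for r in rows])


def _pair_energy(L: int, planted: list[tuple[int, int]], targets: np.ndarray,
                 rep_i: np.ndarray, rep_j: np.ndarray,
                 chain_w: float, planted_w: float, rep_w: float,
                 rep_d0: float = 13.0):
    pi = np.array([p[0] for p in planted], dtype=int)
    pj = np.array([p[1] for p in planted], dtype=int)
    idx = np.arange(L - 1)

    def energy(x: np.ndarray) -> tuple[float, np.ndarray]:
        X = x.reshape(L, 3)
        grad = np.zeros_like(X)
        total = 0.0

        def add(ii, jj, weight, d0, one_sided):
            nonlocal total
            diff = X[ii] - X[jj]
            d = np.sqrt((diff**2).sum(axis=1)) + 1e-12
            delta = d - d0
            if one_sided:
                delta = np.where(delta < 0, delta, 0.0)
            total += weight * (delta**2).sum()
            g = (2.0 * weight * delta / d)[:, None] * diff
            np.add.at(grad, ii, g)
            np.add.at(grad, jj, -g)

        add(idx, idx + 1, chain_w, 3.8, False)
        if len(pi):
            add(pi, pj, planted_w, targets, False)
        if rep_i.size:
            add(rep_i, rep_j, rep_w, rep_d0, True)
        return total, grad.ravel()

    return energy


def _bead_model(X: np.ndarray) -> StructureModel:
    residues = [
        Residue(k + 1, "", "ALA", {"CA": Atom("CA", "C", X[k])})
        for k in range(len(X))
    ]
    return StructureModel("A", residues)


def plant_structure(
    L: int,
    planted_pairs: Sequence[tuple[int, int]],
    mode: str = "bead",
    seed: int = 0,
    max_retries: int = 8,
    min_far_fraction: float = 0.9,
) -> StructureModel:
    """Coordinates with planted pairs in contact.

    ``bead`` mode: one CA bead per residue on a 3.8 A chain; planted pairs
    are pulled to target distances drawn from U(4, 9) A by staged penalised
    least squares while pairs away from the planted contacts (outside a
    +/-2 sequence neighbourhood, which chain continuity forces close) are
    pushed beyond 12 A; a solution is accepted when all planted pairs are
    within 10 A and at least ``min_far_fraction`` of the pushed pairs are
    beyond 12 A.  ``helix_backbone`` mode: an idealised alpha-helical
    backbone for secondary-structure / accessibility work (no planting).
    """
    planted = sorted({(min(i, j), max(i, j)) for i, j in planted_pairs})
    for i, j in planted:
        if not 0 <= i < j < L:
            raise ValueError(f"planted pair ({i}, {j}) out of range")
        if j - i <= 6:
            raise ValueError(f"planted pair ({i}, {j}) violates |i-j| > 6")
    if mode == "helix_backbone":
        if planted:
            raise ValueError("helix_backbone mode does not plant pairs")
        return ideal_helix(L)
    if mode != "bead":
        raise ValueError(f"unknown mode {mode!r}")

    near = set()
    for i, j in planted:
        for di in (-2, -1, 0, 1, 2):
            for dj in (-2, -1, 0, 1, 2):
                a, b = sorted((i + di, j + dj))
                if 0 <= a < b < L:
                    near.add((a, b))
    rep_pairs = [
        (i, j) for i in range(L) for j in range(i + 3, L) if (i, j) not in near
    ]
    rep_i = np.array([p[0] for p in rep_pairs], dtype=int)
    rep_j = np.array([p[1] for p in rep_pairs], dtype=int)

    rng = np.random.default_rng(seed)
    diagnostics = []
    for _ in range(max_retries):
        targets = rng.uniform(4.0, 9.0, size=len(planted))
        steps = rng.standard_normal((L - 1, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        x = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)]).ravel()
        # coarse fold, contact tightening, then bond-length polish
        for cw, pw, rw, iters in (
            (100.0, 100.0, 6.0, 3000),
            (1000.0, 200.0, 8.0, 2000),
            (100000.0, 500.0, 4.0, 2000),
        ):
            energy = _pair_energy(L, planted, targets, rep_i, rep_j, cw, pw, rw)
            x = minimize(
                energy, x, jac=True, method="L-BFGS-B",
                options={"maxiter": iters},
            ).x
        X = x.reshape(L, 3)
        d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(axis=2))
        planted_ok = all(d[i, j] <= 10.0 for i, j in planted)
        far = (
            float(np.mean(d[rep_i, rep_j] > 12.0)) if rep_pairs else 1.0
        )
        if planted_ok and far >= min_far_fraction:
            return _bead_model(X)
        diagnostics.append(f"planted_ok={planted_ok}, far_fraction={far:.2f}")
    raise RuntimeError(
        f"could not realise {len(planted)} planted contacts on L={L} after "
        f"{max_retries} retries: {'; '.join(diagnostics)}"
    )


def compact_chain(
    L: int, seed: int = 0, radius: Optional[float] = None, max_restarts: int = 200
) -> StructureModel:
    """Compact self-avoiding bead chain (3.8 A steps) inside a sphere.

    Grown by rejection: each step keeps 3.8 A spacing, stays at least 3.8 A
    from all earlier non-adjacent beads and inside radius ~ 3.4 L^(1/3).
    The result has a protein-like contact density, from which planted
    coupling pairs can be drawn.
    """
    if radius is None:
        radius = 3.4 * L ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        X = np.zeros((L, 3))
        ok = True
        for k in range(1, L):
            placed = False
            for _try in range(60):
                v = rng.standard_normal(3)
                cand = X[k - 1] + 3.8 * v / np.linalg.norm(v)
                if np.linalg.norm(cand) > radius:
                    continue
                if k >= 2:
                    d = np.linalg.norm(X[: k - 1] - cand, axis=1)
                    if (d < 3.8).any():
                        continue
                X[k] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return _bead_model(X - X.mean(axis=0))
    raise RuntimeError(f"could not grow a compact chain of length {L}")


def contact_pairs(
    s: StructureModel, max_distance: float = 10.0, min_separation: int = 6
) -> list[tuple[int, int]]:
    """Residue pairs within ``max_distance`` and |i-j| > ``min_separation``."""
    X = np.array([r.coord("CA") for r in s.residues])
    d = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(axis=2))
    L = len(X)
    return [
        (i, j)
        for i in range(L)
        for j in range(i + min_separation + 1, L)
        if d[i, j] <= max_distance
    ]


def relabel_beads(s: StructureModel, sequence: str) -> StructureModel:
    """Set bead residue identities to match a representative sequence."""
    if len(sequence) != len(s.residues):
        raise ValueError("sequence length must equal residue count")
    residues = [
        Residue(r.number, r.icode, ONE_TO_THREE.get(ch, "ALA"), dict(r.atoms))
        for r, ch in zip(s.residues, sequence)
    ]
    return StructureModel(s.chain_id, residues)


@dataclass
class PlantedFamily:
    family_id: str
    alignment: Alignment
    structure: StructureModel
    planted_pairs: list[tuple[int, int, float]]  # (i, j, strength)
    field_profile: np.ndarray
    core_columns: list[int]
    hub_columns: list[int]
    seed: int

    def to_family_record(self, structure_path=None) -> FamilyRecord:
        return FamilyRecord(
            family_id=self.family_id,
            alignment=self.alignment,
            representative_id=self.alignment.ids[0],
            structure_path=structure_path,
            chain=self.structure.chain_id,
        )


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    ``field_range`` spans the family-level conservation gradient (multiplier
    on per-column field strengths, weakest first); ``coupling_range`` gives
    the planted coupling counts at the (variable, conserved) ends, so
    coupling density falls as conservation rises.  ``hub_bias`` is the
    probability that a planted coupling attaches to a hub site, and hubs
    carry strong fields (``hub_field``), encoding conserved, highly
    connected sites.
    """

    n_families: int = 24
    L: int = 60
    N: int = 300
    field_range: tuple[float, float] = (0.5, 2.2)
    coupling_range: tuple[int, int] = (20, 6)
    coupling_strength: float = 2.5
    coupling_states: int = 3
    hub_bias: float = 0.95
    hub_fraction: float = 0.045
    hub_field: float = 3.8
    flank_fraction: float = 0.25
    flank_gap_rate: float = 0.30
    sweeps: int = 150
    seed: int = 0


def _coupling_block(
    rng: np.random.Generator,
    strength: float,
    k: int,
    pref_i: int,
    pref_j: int,
) -> np.ndarray:
    """Deviation-only permutation coupling.

    Each non-consensus letter of one column is rewarded with exactly one
    non-consensus letter of the other; the consensus states carry no
    coupling term.  While a site sits at its consensus (the majority of
    sequences) the partner's marginals are untouched, so couplings do not
    transmit conservation; whenever a site deviates, the partner deviates
    in a compensated, detectable way.  The observable covariation
    therefore scales with how often the coupled sites are free to move —
    frozen sites show little signal even when strongly coupled.  ``k`` is
    kept for interface compatibility; the bijection spans the alphabet.
    """
    del k
    from .matrices import similarity_matrix

    sim = similarity_matrix("mclachlan")
    J = np.zeros((20, 20))
    # similarity-coherent bijection: letters similar to one consensus map
    # to letters similar to the other (conservative substitutions
    # compensate conservatively), with small random tie-breaking noise
    rest_i = [a for a in range(20) if a != pref_i]
    rest_j = [b for b in range(20) if b != pref_j]
    order_i = sorted(rest_i, key=lambda a: -(sim[pref_i, a] + 0.3 * rng.random()))
    order_j = sorted(rest_j, key=lambda b: -(sim[pref_j, b] + 0.3 * rng.random()))
    J[order_i, order_j] = strength
    return J


def make_family(
    family_id: str,
    L: int,
    N: int,
    field_scale: float,
    n_couplings: int,
    spec: CohortSpec,
    seed: int,
) -> PlantedFamily:
    """One synthetic family: couplings planted on actual structure contacts.

    The compact bead structure comes first; planted pairs are drawn from
    its contact map (<= 10 A, |i-j| > 6), preferentially from edges
    incident to hub sites — the highest-contact-degree core columns, which
    also receive strong fields.
    """
    rng = np.random.default_rng(seed)
    core_contacts: list[tuple[int, int]] = []
    for attempt in range(10):  # rare seeds yield too few core contacts
        structure = compact_chain(L, seed=seed + 1 + 131 * attempt)
        contacts = contact_pairs(structure)
        n_flank = int(round(spec.flank_fraction * L))
        flank = sorted(rng.choice(L, size=n_flank, replace=False).tolist())
        core = [c for c in range(L) if c not in set(flank)]
        core_set = set(core)
        core_contacts = [
            (i, j) for i, j in contacts if i in core_set and j in core_set
        ]
        if len(core_contacts) >= n_couplings:
            break
    else:
        raise RuntimeError(
            f"only {len(core_contacts)} core contacts for {n_couplings} "
            f"couplings (L={L}, seed={seed})"
        )

    contact_degree = {c: 0 for c in core}
    for i, j in core_contacts:
        contact_degree[i] += 1
        contact_degree[j] += 1
    n_hubs = max(1, int(round(spec.hub_fraction * len(core))))
    hubs = sorted(
        sorted(core, key=lambda c: (-contact_degree[c], c))[:n_hubs]
    )
    hub_set = set(hubs)

    h = np.zeros((L, 20))
    strengths = np.zeros(L)
    preferred = np.zeros(L, dtype=int)
    # hubs stiffen with the family's overall conservation: in conserved
    # families even the hub sites are frozen, which is what limits their
    # observable covariation
    hub_field = spec.hub_field * (0.55 + 0.30 * field_scale)
    for c in core:
        letter = int(rng.integers(0, 20))
        preferred[c] = letter
        s = (
            hub_field * rng.uniform(0.85, 1.15)
            if c in hub_set
            else field_scale * rng.uniform(0.85, 1.15)
        )
        strengths[c] = s
        h[c, letter] = s

    hub_edges = [p for p in core_contacts if p[0] in hub_set or p[1] in hub_set]
    other_edges = [p for p in core_contacts if p not in set(hub_edges)]
    pairs: list[tuple[int, int]] = []
    taken: set[tuple[int, int]] = set()
    attempts = 0
    while len(pairs) < n_couplings and attempts < 5000:
        attempts += 1
        use_hub = hub_edges and (rng.random() < spec.hub_bias or not other_edges)
        edge = (
            hub_edges[rng.integers(len(hub_edges))]
            if use_hub
            else other_edges[rng.integers(len(other_edges))]
        )
        if edge in taken:
            continue
        taken.add(edge)
        pairs.append(edge)
    pairs.sort()
    # graded coupling strengths give a continuous score tail, as in real
    # families where contact couplings vary in strength
    edge_strength = {
        p: spec.coupling_strength * rng.uniform(0.9, 1.25) for p in pairs
    }
    J = {
        (i, j): _coupling_block(
            rng, edge_strength[(i, j)], spec.coupling_states,
            preferred[i], preferred[j],
        )
        for i, j in pairs
    }
    # deviation-only couplings add ~log(1 + (e^s - 1)/19) of effective
    # anti-consensus field per edge (a variable partner matches one of the
    # 19 rewarded deviations); hubs are compensated so their conservation
    # stays at the level their field encodes, while non-hub partners are
    # left to absorb the pressure — coupling-rich columns drift toward
    # variability, as coupling-rich families do
    for (i, j), s_e in edge_strength.items():
        comp = np.log1p((np.exp(s_e) - 1.0) / 19.0)
        if i in hub_set:
            h[i, preferred[i]] += comp
        if j in hub_set:
            h[j, preferred[j]] += comp
    params = PottsCouplings(L=L, q=20, h=h, J=J)
    ids = [f"{family_id}_rep"] + [f"{family_id}_s{k}" for k in range(1, N)]
    aln = sample_potts_alignment(L, N, params, sweeps=spec.sweeps,
                                 seed=seed + 2, ids=ids)
    aln = inject_gaps(aln, flank, spec.flank_gap_rate, seed=seed + 3)
    structure = relabel_beads(structure, aln.rows[0])
    return PlantedFamily(
        family_id=family_id,
        alignment=aln,
        structure=structure,
        planted_pairs=[(i, j, edge_strength[(i, j)]) for i, j in pairs],
        field_profile=strengths,
        core_columns=core,
        hub_columns=hubs,
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> list[PlantedFamily]:
    """Families spanning the conservation gradient, coupling density
    anti-correlated with field strength."""
    fams = []
    scales = np.linspace(*spec.field_range, spec.n_families)
    counts = np.round(np.linspace(*spec.coupling_range, spec.n_families)).astype(int)
    for k in range(spec.n_families):
        fid = f"SYN{k:03d}"
        fams.append(
            make_family(
                fid, spec.L, spec.N, float(scales[k]), int(counts[k]),
                spec, seed=spec.seed + 1000 * (k + 1),
            )
        )
    return fams


def assign_synthetic_go(
    cohort: Sequence[PlantedFamily],
    classes: dict[str, list[str]],
    trend_map: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> "pd.DataFrame":
    """Deterministic annotation table for stratified-regression fixtures.

    ``classes`` maps each annotation domain to its class labels.  With an
    empty ``trend_map`` labels are uniform random; a ``trend_map`` bias in
    [-1, 1] skews a label toward families with many (positive bias) or few
    (negative bias) planted couplings.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    trend_map = trend_map or {}
    counts = np.array([len(f.planted_pairs) for f in cohort], dtype=float)
    if np.ptp(counts) > 0:
        rank = (counts - counts.min()) / np.ptp(counts)
    else:
        rank = np.full(len(cohort), 0.5)
    rows = []
    for domain, labels in classes.items():
        for fam, r in zip(cohort, rank):
            logits = np.array(
                [3.0 * trend_map.get(lbl, 0.0) * (r - 0.5) for lbl in labels]
            )
            p = np.exp(logits - logits.max())
            p /= p.sum()
            lbl = labels[rng.choice(len(labels), p=p)]
            rows.append({"family_id": fam.family_id, "domain": domain, "label": lbl})
    return pd.DataFrame(rows, columns=["family_id", "domain", "label"])


def write_family(fam: PlantedFamily, outdir) -> dict[str, Path]:
    """Write FASTA + PDB (+ per-family metadata) like real inputs."""
    from .alignment import write_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{fam.family_id}.fasta"
    write_alignment(fam.alignment, fasta)
    pdb = outdir / f"{fam.family_id}.pdb"
    with open(pdb, "w") as fh:
        serial = 1
        for res in fam.structure.residues:
            for atom in res.atoms.values():
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {name} {res.name3:>3s} "
                    f"{fam.structure.chain_id}{res.number:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")
    return {"fasta": fasta, "pdb": pdb}
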