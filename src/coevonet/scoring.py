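"""Covariation scoring: mutual information (MIp), McBASC, Z-scores, pairs.

All scorers return a :class:`ScoreMatrix` — a symmetric L x L matrix with a
validity mask (diagonal and unscoreable pairs are invalid).  Standardisation
to Z-scores is always per family, per method, over the valid upper triangle
of that family's matrix, and significance uses the Z >= 4 convention with a
minimum sequence separation shared with the null-pair sampler.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .alignment import Alignment
from .matrices import similarity_matrix

METHODS = ("MIp", "McBASC", "DCA", "PSICOV")


@dataclass
class ScoreMatrix:
    """Symmetric per-pair covariation scores for one family and method."""

    method: str
    values: np.ndarray
    valid: np.ndarray
    standardized: bool = False
    no_variance: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("score matrix must be symmetric")
        self.values = v
        self.valid = np.asarray(self.valid, dtype=bool)
        np.fill_diagonal(self.valid, False)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def upper_valid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, score) arrays over the valid upper triangle."""
        iu, ju = np.triu_indices(self.L, k=1)
        keep = self.valid[iu, ju]
        return iu[keep], ju[keep], self.values[iu[keep], ju[keep]]


@dataclass(frozen=True, order=True)
class SignificantPair:
    """A coevolved column pair (i < j, 0-based) with its Z-score."""

    i: int
    j: int
    method: str = field(compare=False)
    z: float = field(compare=False)


def pairwise_identity(codes: np.ndarray, block: int = 256) -> np.ndarray:
    """Fraction of identical positions for every pair of aligned rows."""
    n, L = codes.shape
    out = np.empty((n, n))
    for start in range(0, n, block):
        stop = min(start + block, n)
        eq = codes[start:stop, None, :] == codes[None, :, :]
        out[start:stop] = eq.mean(axis=2)
    return out


def sequence_weights(
    a: Alignment, identity_threshold: float = 0.8
) -> tuple[np.ndarray, float]:
    """Inverse-cluster-size weights: w_k = 1 / #{l : id(k,l) >= t}.

    Returns the per-sequence weights and the effective sequence count
    Meff = sum(w).
    """
    ident = pairwise_identity(a.codes)
    neighbors = (ident >= identity_threshold).sum(axis=1)
    w = 1.0 / neighbors
    return w, float(w.sum())


def _residue_valid(codes: np.ndarray) -> np.ndarray:
    """True where the symbol is one of the 20 amino acids."""
    return codes < 20


def mutual_information(
    a: Alignment,
    weights: Optional[np.ndarray] = None,
    min_joint_count: int = 20,
) -> ScoreMatrix:
    """Plug-in mutual information (bits) between all column pairs.

    Frequencies are taken over sequences with a standard residue at BOTH
    columns (pairwise-complete gap policy); pairs with fewer than
    ``min_joint_count`` usable sequences are masked invalid.
    """
    if a.N < 2:
        raise ValueError("mutual information needs at least 2 sequences")
    codes = a.codes
    N, L = codes.shape
    w = np.ones(N) if weights is None else np.asarray(weights, dtype=float)
    ok = _residue_valid(codes)

    # weighted one-hot per column; invalid symbols contribute zero rows
    onehot = np.zeros((L, N, 20))
    for c in range(L):
        rows = np.nonzero(ok[:, c])[0]
        onehot[c, rows, codes[rows, c]] = w[rows]
    mask_w = np.where(ok, w[:, None], 0.0)  # (N, L) weight if valid

    mi = np.zeros((L, L))
    valid = np.zeros((L, L), dtype=bool)
    okf = ok.astype(float)
    for i in range(L):
        for j in range(i + 1, L):
            both = ok[:, i] & ok[:, j]
            if int(both.sum()) < min_joint_count:
                continue
            wij = w[both]
            joint = onehot[i][both].T @ (codes[both, j][:, None] == np.arange(20)[None, :])
            total = wij.sum()
            p = joint / total
            pi = p.sum(axis=1)
            pj = p.sum(axis=0)
            nz = p > 0
            mi_ij = float(
                (p[nz] * np.log2(p[nz] / np.outer(pi, pj)[nz])).sum()
            )
            mi[i, j] = mi[j, i] = max(mi_ij, 0.0)
            valid[i, j] = valid[j, i] = True
    return ScoreMatrix("MI", mi, valid)


def apc_correct(mi: ScoreMatrix, method: Optional[str] = None) -> ScoreMatrix:
    """Average-product correction: s(i,j) - s(i,.)s(j,.)/<s>."""
    if mi.standardized:
        raise ValueError("APC applies to raw scores")
    if method is None:
        method = "MIp" if mi.method == "MI" else mi.method
    vals, valid = mi.values, mi.valid
    L = mi.L
    out = np.zeros((L, L))
    row_sum = np.where(valid, vals, 0.0).sum(axis=1)
    row_n = valid.sum(axis=1)
    iu, ju = np.triu_indices(L, k=1)
    keep = valid[iu, ju]
    if keep.sum() == 0:
        return ScoreMatrix(method, out, valid)
    grand_mean = vals[iu[keep], ju[keep]].mean()
    if grand_mean == 0.0:
        return ScoreMatrix(method, out, valid)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_mean = np.where(row_n > 0, row_sum / np.maximum(row_n, 1), 0.0)
    apc = np.outer(row_mean, row_mean) / grand_mean
    out = np.where(valid, vals - apc, 0.0)
    out = 0.5 * (out + out.T)
    return ScoreMatrix(method, out, valid)


def mip_score(
    a: Alignment,
    weights: Optional[np.ndarray] = None,
    min_joint_count: int = 20,
) -> ScoreMatrix:
    """Mutual information with average-product correction (MIp)."""
    return apc_correct(mutual_information(a, weights, min_joint_count))


def mcbasc_score(a: Alignment, similarity: str | np.ndarray = "mclachlan") -> ScoreMatrix:
    """McBASC-style score: Pearson correlation of substitution-similarity
    tables.

    For column i the table S_i(k,l) = M(a_ki, a_li) is built over all ordered
    sequence pairs (k,l); score(i,j) is the correlation of S_i and S_j over
    entries where both columns carry standard residues for both sequences.
    Fully conserved columns (zero variance) score 0 by convention.
    """
    if a.N < 2:
        raise ValueError("McBASC needs at least 2 sequences")
    sim = (
        similarity_matrix(similarity)
        if isinstance(similarity, str)
        else np.asarray(similarity, dtype=float)
    )
    codes = a.codes
    N, L = codes.shape
    ok = _residue_valid(codes)

    n2 = N * N
    X = np.zeros((L, n2))
    V = np.zeros((L, n2))
    safe = np.where(ok, codes, 0)
    for c in range(L):
        table = sim[safe[:, c]][:, safe[:, c]]
        vmask = np.outer(ok[:, c], ok[:, c]).astype(float)
        X[c] = (table * vmask).ravel()
        V[c] = vmask.ravel()

    n = V @ V.T
    sxy = X @ X.T
    sx = X @ V.T          # sum of X_i over entries valid in both i and j
    sxx = (X * X) @ V.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        cov = sxy / n - mean_x * mean_x.T
        var = sxx / n - mean_x**2
        denom = np.sqrt(var * var.T)
        corr = np.where(denom > 0, cov / denom, 0.0)
    corr = np.nan_to_num(corr)
    corr = 0.5 * (corr + corr.T)
    np.clip(corr, -1.0, 1.0, out=corr)
    valid = n >= 4  # at least two usable sequences in both columns
    return ScoreMatrix("McBASC", np.where(valid, corr, 0.0), valid)


def zscore_standardize(s: ScoreMatrix) -> ScoreMatrix:
    """Standardise valid upper-triangle scores to mean 0, population SD 1."""
    if s.standardized:
        raise ValueError("matrix already standardized")
    _, _, scores = s.upper_valid()
    if scores.size < 2:
        raise ValueError("need at least 2 valid pairs to standardize")
    mu = scores.mean()
    sd = scores.std()
    L = s.L
    if sd == 0.0:
        return ScoreMatrix(s.method, np.zeros((L, L)), s.valid,
                           standardized=True, no_variance=True)
    z = np.where(s.valid, (s.values - mu) / sd, 0.0)
    return ScoreMatrix(s.method, z, s.valid, standardized=True)


def select_significant_pairs(
    z: ScoreMatrix,
    z_cutoff: float = 4.0,
    min_sequence_separation: int = 6,
) -> list[SignificantPair]:
    """Pairs with z >= cutoff and |i-j| >= separation, sorted by -z then (i,j)."""
    if not z.standardized:
        raise ValueError("select_significant_pairs expects a standardized matrix")
    iu, ju, scores = z.upper_valid()
    keep = (scores >= z_cutoff) & ((ju - iu) >= min_sequence_separation)
    pairs = [
        SignificantPair(int(i), int(j), z.method, float(s))
        for i, j, s in zip(iu[keep], ju[keep], scores[keep])
    ]
    pairs.sort(key=lambda p: (-p.z, p.i, p.j))
    return pairs


def method_overlap(
    pairsets: dict[str, Sequence[SignificantPair]]
) -> "pd.DataFrame":
    """Pairwise Jaccard index of significant (i, j) sets between methods."""
    import pandas as pd

    if len(pairsets) < 2:
        raise ValueError("need at least two methods to compare")
    names = list(pairsets)
    sets = {m: {(p.i, p.j) for p in pairsets[m]} for m in names}
    out = np.eye(len(names))
    for a_i, b_i in itertools.combinations(range(len(names)), 2):
        sa, sb = sets[names[a_i]], sets[names[b_i]]
        union = len(sa | sb)
        jac = len(sa & sb) / union if union else 0.0
        out[a_i, b_i] = out[b_i, a_i] = jac
    return pd.DataFrame(out, index=names, columns=names)


def write_score_tsv(s: ScoreMatrix, z: ScoreMatrix, path) -> None:
    """Write per-pair raw and Z scores (1-based positions)."""
    iu, ju, raw = s.upper_valid()
    zvals = z.values[iu, ju]
    with open(path, "w") as fh:
        fh.write("i\tj\traw\tz\tmethod\n")
        for i, j, r, zv in zip(iu, ju, raw, zvals):
            fh.write(f"{i + 1}\t{j + 1}\t{r:.6g}\t{zv:.6g}\t{s.method}\n")


def write_pairs_tsv(pairs: Iterable[SignificantPair], path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write("i\tj\tz\tmethod\n")
        for p in pairs:
            fh.write(f"{p.i + 1}\t{p.j + 1}\t{p.z:.6g}\t{p.method}\n")
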