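"""Per-column conservation index (CI).

The raw score of a column is a sequence-weighted sum-of-pairs over a
substitution matrix (BLOSUM62 by default), computed over sequence pairs
with standard residues at that column; weights follow an independent-count
scheme (inverse cluster size at 80% identity, normalised to sum 1).  Raw
scores are z-normalised over unmasked columns of the family so that a CI of
0 is a column of average conservation and positive values are more
conserved — the scale on which family averages such as 0.65 or 1.63 live.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .alignment import Alignment
from .matrices import similarity_matrix
from .scoring import pairwise_identity


@dataclass
class ConservationProfile:
    """Raw and normalised per-column conservation with a column mask."""

    raw: np.ndarray
    ci: np.ndarray
    gap_mask: np.ndarray  # True where the column is excluded
    no_variance: bool = False

    @property
    def L(self) -> int:
        return self.raw.size

    def unmasked(self) -> np.ndarray:
        return np.nonzero(~self.gap_mask)[0]


def independent_count_weights(
    a: Alignment, identity_threshold: float = 0.8
) -> np.ndarray:
    """Inverse-cluster-size weights normalised to sum 1."""
    ident = pairwise_identity(a.codes)
    w = 1.0 / (ident >= identity_threshold).sum(axis=1)
    return w / w.sum()


def sum_of_pairs_raw(
    a: Alignment,
    weights: Optional[np.ndarray] = None,
    matrix: str | np.ndarray = "blosum62",
    gap_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sum-of-pairs raw conservation per column.

    raw(c) = sum_{k<l} w_k w_l M(a_kc, a_lc) / sum_{k<l} w_k w_l over
    sequence pairs with standard residues at c.  Columns whose gap fraction
    exceeds ``gap_threshold``, or with fewer than two scoreable residues,
    are masked.  Returns (raw, mask).
    """
    if a.N < 2:
        raise ValueError("sum-of-pairs needs at least 2 sequences")
    if weights is None:
        weights = independent_count_weights(a)
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    M = (
        similarity_matrix(matrix)
        if isinstance(matrix, str)
        else np.asarray(matrix, dtype=float)
    )
    codes = a.codes
    N, L = codes.shape
    ok = codes < 20
    raw = np.zeros(L)
    mask = np.zeros(L, dtype=bool)
    gap_frac = (codes == 20).mean(axis=0)
    for c in range(L):
        rows = np.nonzero(ok[:, c])[0]
        if rows.size < 2 or gap_frac[c] > gap_threshold:
            mask[c] = True
            continue
        wc = w[rows]
        sub = M[np.ix_(codes[rows, c], codes[rows, c])]
        ww = np.outer(wc, wc)
        iu = np.triu_indices(rows.size, k=1)
        raw[c] = float((ww[iu] * sub[iu]).sum() / ww[iu].sum())
    return raw, mask


def normalize_profile(raw: np.ndarray, mask: np.ndarray) -> ConservationProfile:
    """Z-normalise raw scores over unmasked columns (population SD)."""
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    idx = np.nonzero(~mask)[0]
    if idx.size < 2:
        raise ValueError("need at least 2 unmasked columns to normalize")
    mu = raw[idx].mean()
    sd = raw[idx].std()
    ci = np.zeros_like(raw)
    if sd == 0.0:
        return ConservationProfile(raw, ci, mask, no_variance=True)
    ci[idx] = (raw[idx] - mu) / sd
    return ConservationProfile(raw, ci, mask)


def conservation_profile(
    a: Alignment,
    matrix: str | np.ndarray = "blosum62",
    identity_threshold: float = 0.8,
    gap_threshold: float = 0.5,
) -> ConservationProfile:
    """Full pipeline: weights -> sum-of-pairs -> normalised CI."""
    w = independent_count_weights(a, identity_threshold)
    raw, mask = sum_of_pairs_raw(a, w, matrix, gap_threshold)
    return normalize_profile(raw, mask)


def family_average_conservation(
    p: ConservationProfile, cols: Iterable[int]
) -> float:
    """Mean CI over the requested columns, ignoring masked ones."""
    cols = sorted(set(cols) & set(p.unmasked().tolist()))
    if not cols:
        raise ValueError("no unmasked columns in the requested set")
    return float(p.ci[cols].mean())


def write_profile_tsv(p: ConservationProfile, a: Alignment, path) -> None:
    gap_frac = (a.codes == 20).mean(axis=0)
    with open(path, "w") as fh:
        fh.write("column\traw\tci\tgap_fraction\tmasked\n")
        for c in range(p.L):
            ci = "" if p.gap_mask[c] else f"{p.ci[c]:.6g}"
            fh.write(
                f"{c + 1}\t{p.raw[c]:.6g}\t{ci}\t{gap_frac[c]:.4g}\t"
                f"{int(p.gap_mask[c])}\n"
            )
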