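"""Mean-field direct coupling analysis (DCA).

Infers a maximum-entropy (Potts) model from the alignment by inverting the
pseudocount-regularised connected-correlation matrix, then scores every
column pair by direct information (DI): the Kullback-Leibler divergence
between the two-site direct model and the product of its marginals.  The
alphabet has q = 21 states (20 amino acids + gap; unknown residues are
treated as gaps).  Reported DI is in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import Alignment
from .scoring import ScoreMatrix, sequence_weights

Q = 21  # 20 residues + gap


@dataclass
class PottsCouplings:
    """Fields h (L x q) and sparse couplings J[(i, j)] -> q x q.

    J is stored once per unordered pair (i < j); J[(j, i)] is implied by
    the symmetry J_ij(a, b) = J_ji(b, a).
    """

    L: int
    q: int = 20
    h: np.ndarray = None
    J: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.h is None:
            self.h = np.zeros((self.L, self.q))
        self.h = np.asarray(self.h, dtype=float)
        if self.h.shape != (self.L, self.q):
            raise ValueError("field matrix must be (L, q)")
        norm = {}
        for (i, j), block in self.J.items():
            block = np.asarray(block, dtype=float)
            if block.shape != (self.q, self.q):
                raise ValueError("coupling blocks must be (q, q)")
            if i == j:
                raise ValueError("self-couplings are not allowed")
            if i > j:
                i, j, block = j, i, block.T
            norm[(i, j)] = block
        self.J = norm

    def coupling(self, i: int, j: int) -> np.ndarray:
        if i < j:
            return self.J.get((i, j), np.zeros((self.q, self.q)))
        return self.J.get((j, i), np.zeros((self.q, self.q))).T

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.J)


def _frequencies(
    a: Alignment, weights: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reweighted, pseudocount-mixed single and pair frequencies (q=21)."""
    codes = np.where(a.codes >= 20, 20, a.codes)  # gap and X share state 20
    N, L = codes.shape
    w = weights / weights.sum()
    onehot = np.zeros((N, L * Q))
    flat = (codes + Q * np.arange(L)).ravel()
    onehot[np.repeat(np.arange(N), L), flat] = 1.0
    fi = (w[:, None] * onehot).sum(axis=0).reshape(L, Q)
    fij = (onehot * w[:, None]).T @ onehot
    fij = fij.reshape(L, Q, L, Q).transpose(0, 2, 1, 3)

    lam = pseudocount
    fi = (1 - lam) * fi + lam / Q
    fij = (1 - lam) * fij + lam / (Q * Q)
    # self blocks are diagonal in the true statistics and in the prior
    for i in range(L):
        fij[i, i] = np.diag(fi[i])
    return fi, fij


def _direct_information(W: np.ndarray, fi: np.ndarray, fj: np.ndarray,
                        tol: float = 1e-6, max_iter: int = 500) -> float:
    """DI of one pair from its direct-coupling matrix W = exp(-invC block).

    The single-site terms are fixed by self-consistency so that the
    two-site direct model reproduces the pseudocounted marginals.
    """
    mu1 = np.full(Q, 1.0 / Q)
    mu2 = np.full(Q, 1.0 / Q)
    for _ in range(max_iter):
        s1 = W @ mu2
        s2 = W.T @ mu1
        new1 = fi / s1
        new1 /= new1.sum()
        new2 = fj / s2
        new2 /= new2.sum()
        diff = max(np.abs(new1 - mu1).max(), np.abs(new2 - mu2).max())
        mu1, mu2 = new1, new2
        if diff < tol:
            break
    pdir = W * np.outer(mu1, mu2)
    pdir /= pdir.sum()
    prod = np.outer(fi, fj)
    nz = pdir > 1e-100
    return float((pdir[nz] * np.log2(pdir[nz] / prod[nz])).sum())


def dca_direct_information(
    a: Alignment,
    identity_threshold: float = 0.8,
    pseudocount_weight: float = 0.5,
    weights: Optional[np.ndarray] = None,
) -> ScoreMatrix:
    """Mean-field DCA direct information for all column pairs (bits)."""
    if a.N < 2 or a.L < 2:
        raise ValueError("DCA needs at least 2 sequences and 2 columns")
    if weights is None:
        weights, _ = sequence_weights(a, identity_threshold)
    fi, fij = _frequencies(a, weights, pseudocount_weight)
    L = a.L

    # connected correlations over q-1 states (gap state dropped per column)
    qr = Q - 1
    C = np.empty((L * qr, L * qr))
    for i in range(L):
        for j in range(L):
            block = fij[i, j, :qr, :qr] - np.outer(fi[i, :qr], fi[j, :qr])
            C[i * qr:(i + 1) * qr, j * qr:(j + 1) * qr] = block
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            f"correlation matrix singular (L={L}, pseudocount="
            f"{pseudocount_weight}); increase the pseudocount"
        ) from exc

    di = np.zeros((L, L))
    W = np.ones((Q, Q))
    for i in range(L):
        for j in range(i + 1, L):
            W[:qr, :qr] = np.exp(
                -invC[i * qr:(i + 1) * qr, j * qr:(j + 1) * qr]
            )
            W[qr, :] = 1.0
            W[:, qr] = 1.0
            di[i, j] = di[j, i] = _direct_information(W, fi[i], fi[j])
    valid = np.ones((L, L), dtype=bool)
    return ScoreMatrix("DCA", di, valid)
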