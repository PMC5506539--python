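"""Sparse inverse-covariance contact scoring (PSICOV-style).

Columns are one-hot encoded over the 20 standard residues (gaps contribute
zero rows), sequence-reweighted, and the 20L x 20L sample covariance is
shrunk toward its diagonal until positive definite.  A sparse precision
matrix is then estimated by L1-penalised maximum likelihood (graphical
lasso) and each column pair is scored by the L1 norm of its 20 x 20
precision block, followed by average-product correction.

Zero-variance coordinates (residue states never observed in a column) are
dropped before estimation; their precision rows are exactly diagonal, so
this leaves pair scores unchanged while shrinking the problem.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .alignment import Alignment
from .scoring import ScoreMatrix, apc_correct, sequence_weights


class PsicovConvergenceError(RuntimeError):
    """Graphical lasso failed to produce a usable precision matrix."""


def _onehot(a: Alignment, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    codes = a.codes
    N, L = codes.shape
    X = np.zeros((N, 20 * L))
    ok = codes < 20
    rows, cols = np.nonzero(ok)
    X[rows, codes[rows, cols] + 20 * cols] = 1.0
    w = weights / weights.sum()
    return X, w


def psicov_score(
    a: Alignment,
    regularization: float = 0.003,
    shrinkage: float = 0.3,
    identity_threshold: float = 0.8,
    weights: Optional[np.ndarray] = None,
    max_iter: int = 15,
    tol: float = 5e-3,
    enet_tol: float = 1e-4,
) -> ScoreMatrix:
    """Graphical-lasso pair scores with average-product correction.

    The default iteration cap stops the solver well before full dual-gap
    convergence: the block L1 pair scores (and their ranking) stabilise
    within a few iterations, long before the precision entries do.
    """
    if a.N < 2 or a.L < 2:
        raise ValueError("PSICOV needs at least 2 sequences and 2 columns")
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    if weights is None:
        weights, _ = sequence_weights(a, identity_threshold)
    X, w = _onehot(a, weights)
    mean = w @ X
    Xc = X - mean
    cov = (Xc * w[:, None]).T @ Xc
    L = a.L

    var = np.diag(cov).copy()
    keep = var > 1e-12
    cov = cov[np.ix_(keep, keep)]
    if cov.shape[0] < 2:
        raise PsicovConvergenceError("fewer than two variable residue states")

    diag = np.diag(np.diag(cov))
    gamma = shrinkage
    prec = None
    last_exc: Exception | None = None
    while gamma <= 1.0:
        shrunk = (1.0 - gamma) * cov + gamma * diag
        eigmin = np.linalg.eigvalsh(shrunk)[0]
        if eigmin > 1e-10:
            try:
                with warnings.catch_warnings():
                    # the iteration cap is deliberate; partial convergence
                    # is the documented operating mode
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    _, prec = graphical_lasso(
                        shrunk, alpha=regularization, max_iter=max_iter,
                        tol=tol, enet_tol=enet_tol,
                    )
                break
            except FloatingPointError as exc:
                last_exc = exc
        gamma *= 2.0
    if prec is None:
        raise PsicovConvergenceError(
            f"graphical lasso failed up to shrinkage {gamma:.3g} "
            f"(alpha={regularization}, max_iter={max_iter}): {last_exc}"
        )

    full = np.zeros((20 * L, 20 * L))
    idx = np.nonzero(keep)[0]
    full[np.ix_(idx, idx)] = prec
    blocks = np.abs(full).reshape(L, 20, L, 20).sum(axis=(1, 3))
    np.fill_diagonal(blocks, 0.0)
    raw = ScoreMatrix("PSICOV", blocks, np.ones((L, L), dtype=bool))
    return apc_correct(raw)
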