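"""Count matrices, connectivity and the reversible MSM maximum-likelihood
estimator.

These are the single-ensemble building blocks under the multi-ensemble
estimator: transition counting at a lag (sliding window), largest connected
set of the symmetrized count graph, and the standard self-consistent
fixed-point iteration for the reversible transition-matrix MLE

    x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)

whose normalized row sums give the stationary distribution.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "count_matrix",
    "largest_connected_set",
    "reversible_mle",
    "stationary_distribution",
]


def count_matrix(dtrajs: list[np.ndarray], lag: int, n_states: int) -> np.ndarray:
    """Sliding-window transition counts at integer lag."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    C = np.zeros((n_states, n_states))
    for d in dtrajs:
        d = np.asarray(d)
        if len(d) <= lag:
            continue
        np.add.at(C, (d[:-lag], d[lag:]), 1.0)
    return C


def largest_connected_set(C: np.ndarray, directed: bool = False) -> np.ndarray:
    """State indices of the largest connected component of the count graph."""
    adj = (C + C.T) > 0 if not directed else C > 0
    n_comp, labels = connected_components(adj, directed=directed,
                                          connection="strong")
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == np.argmax(sizes))


def reversible_mle(
    C: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood reversible transition matrix from counts.

    Returns (T, pi).  The count matrix must be connected; rows with zero
    counts are not allowed.
    """
    C = np.asarray(C, float)
    n = C.shape[0]
    c_i = C.sum(axis=1)
    if np.any(c_i == 0):
        raise ValueError("count matrix has empty rows; restrict to the "
                         "connected set first")
    S = C + C.T
    x = C.copy()
    x[(S > 0) & (x == 0)] = 1e-10  # keep the support of S
    x_i = x.sum(axis=1)
    mask = S > 0
    for _ in range(max_iter):
        a = c_i / x_i
        denom = a[:, None] + a[None, :]  # c_i/x_i + c_j/x_j
        x_new = np.where(mask, S / np.where(mask, denom, 1.0), 0.0)
        x_new_i = x_new.sum(axis=1)
        delta = np.max(np.abs(x_new_i / x_new_i.sum() - x_i / x_i.sum()))
        x, x_i = x_new, x_new_i
        if delta < tol:
            break
    T = x / x_i[:, None]
    pi = x_i / x_i.sum()
    return T, pi


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Solved as the null space of (T' - I) via SVD, which is robust where the
    non-symmetric eigensolver can fail to converge.
    """
    n = T.shape[0]
    _, s, vt = np.linalg.svd(T.T - np.eye(n))
    null = s < 1e-10 * max(s[0], 1.0)
    rows = vt[null] if null.any() else vt[-1:]
    # reducible chains have a multi-dimensional stationary space; return a
    # strictly positive combination
    pi = np.abs(rows).sum(axis=0)
    return pi / pi.sum()
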