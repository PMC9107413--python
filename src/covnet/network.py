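"""Joint-variation covariance networks and proportional thresholding.

Each subject's network has edge weight

    w_ij = exp(-(z_i - z_j)^2),   i != j,

between the z-scored morphometric values of regions i and j: weights lie
in (0, 1] and equal 1 exactly when the two regions deviate from the
control norm identically.  Binary graphs are obtained by keeping the top
fraction d of the n(n-1)/2 possible edges (proportional density), with a
deterministic tie policy so thresholded edge sets are nested across
densities.
"""

from __future__ import annotations

import numpy as np


def build_network(z: np.ndarray, region_names: list[str] | None = None) -> np.ndarray:
    """Joint-variation weight matrix for one subject's z-score vector.

    Returns an (n, n) symmetric matrix with zero diagonal and off-diagonal
    entries exp(-(z_i - z_j)^2) in (0, 1].
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1:
        raise ValueError("z must be a 1-D vector of z-scores")
    bad = np.flatnonzero(~np.isfinite(z))
    if bad.size:
        names = (
            [region_names[i] for i in bad]
            if region_names is not None
            else bad.tolist()
        )
        raise ValueError(f"non-finite z-score in region(s): {names}")
    diff = z[:, None] - z[None, :]
    W = np.exp(-(diff**2))
    np.fill_diagonal(W, 0.0)
    return W


def n_edges_at_density(d: float, n_nodes: int) -> int:
    """Edge count kept at proportional density d: round-half-away-from-zero
    of d * n(n-1)/2."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(d * m + 0.5))


def _ranked_pairs(W: np.ndarray):
    """Upper-triangle pairs ordered by (weight desc, row asc, col asc)."""
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def threshold_at_density(W: np.ndarray, d: float) -> np.ndarray:
    """Binarize a weight matrix at proportional density d in (0, 1].

    The strongest round(d * n(n-1)/2) undirected pairs become edges; ties
    at the cutoff are broken by (weight desc, row index, column index), so
    edge sets are nested across densities.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if not 0.0 < d <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {d}")
    n = W.shape[0]
    k = n_edges_at_density(d, n)
    ri, rj = _ranked_pairs(W)
    A = np.zeros((n, n), dtype=np.uint8)
    A[ri[:k], rj[:k]] = 1
    A[rj[:k], ri[:k]] = 1
    return A


def realized_density(A: np.ndarray) -> float:
    n = A.shape[0]
    return float(np.triu(A, k=1).sum() / (n * (n - 1) / 2))


def density_grid(start: float = 0.10, stop: float = 0.40, step: float = 0.01) -> np.ndarray:
    """Ordered density grid; default 0.10..0.40 in steps of 0.01 (31 points)."""
    if not (0.0 < start <= stop <= 1.0):
        raise ValueError("grid must satisfy 0 < start <= stop <= 1")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    grid = grid[grid <= stop + 1e-12]
    if np.any(np.diff(grid) <= 0):
        raise ValueError("densities must be strictly increasing")
    return grid
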