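"""Binary graph metrics, degree-preserving nulls, and density profiles.

Global metrics follow the standard small-world recipe: mean Watts-Strogatz
clustering C and characteristic path length L are normalized by their
means over degree-preserving (Maslov-Sneppen rewired) random graphs,

    gamma = C / <C_rand>,  lambda = L / <L_rand>,  sigma = gamma / lambda,

with sigma > 1.1 the conventional small-world signature.  Local metrics
are nodal clustering, local efficiency (global efficiency of the subgraph
induced by a node's neighbors) and degree.  Every metric is evaluated on
the binary graph at each density of a grid, and summarized by the
trapezoidal area under the metric-versus-density curve (AUC).

Path length averages over mutually reachable ordered pairs only, so
fragmented low-density graphs contribute their within-component distances
rather than infinities; restriction to the largest connected component is
available as an alternative policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .network import threshold_at_density


# ---------------------------------------------------------------------------
# local metrics

def nodal_degree(A: np.ndarray) -> np.ndarray:
    """Degree of every node (row sums of the adjacency matrix)."""
    A = np.asarray(A)
    return A.sum(axis=1).astype(np.int64)


def clustering_coefficient(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Watts-Strogatz nodal clustering and its unweighted network mean.

    c_i = 2 * t_i / (k_i (k_i - 1)) with t_i the number of triangles at
    node i; nodes with degree < 2 get 0.
    """
    Af = np.asarray(A, dtype=float)
    k = Af.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", Af, Af, Af) / 2.0
    denom = k * (k - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c, float(c.mean())


def _distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(np.asarray(A, dtype=np.uint8)), method="D", unweighted=True)


def characteristic_path_length(A: np.ndarray, policy: str = "reachable") -> float:
    """Mean shortest-path length over reachable ordered pairs.

    policy="reachable" (default): average over all mutually reachable
    pairs of distinct nodes, excluding unreachable pairs.
    policy="largest_component": restrict to the largest connected
    component first.
    policy="harmonic": harmonic mean over ALL pairs of distinct nodes
    (reciprocal of mean inverse distance, with 1/inf = 0), which penalizes
    disconnection instead of silently dropping the unreachable pairs.
    """
    A = np.asarray(A)
    if A.sum() == 0:
        raise ValueError("characteristic path length undefined for an edgeless graph")
    if policy == "harmonic":
        return 1.0 / global_efficiency(A)
    if policy == "largest_component":
        ncomp, labels = connected_components(csr_matrix(A), directed=False)
        if ncomp > 1:
            largest = np.bincount(labels).argmax()
            A = A[np.ix_(labels == largest, labels == largest)]
    elif policy != "reachable":
        raise ValueError("policy must be 'reachable', 'largest_component' or 'harmonic'")
    D = _distances(A)
    off = ~np.eye(A.shape[0], dtype=bool)
    finite = np.isfinite(D) & off
    return float(D[finite].mean())


def global_efficiency(A: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered pairs (1/inf = 0)."""
    A = np.asarray(A)
    n = A.shape[0]
    if n < 2:
        return 0.0
    D = _distances(A)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(A: np.ndarray, node: int | None = None):
    """Local efficiency: global efficiency of the neighbor-induced subgraph.

    With ``node`` given, returns that node's value; otherwise a vector for
    all nodes.  Nodes with degree < 2 get 0.
    """
    A = np.asarray(A)

    def one(i: int) -> float:
        nb = np.flatnonzero(A[i])
        if nb.size < 2:
            return 0.0
        return global_efficiency(A[np.ix_(nb, nb)])

    if node is not None:
        return one(int(node))
    return np.array([one(i) for i in range(A.shape[0])])


# ---------------------------------------------------------------------------
# degree-preserving null model

def _rewire_kernel(adj, edges, e1, e2, side):  # pragma: no cover - jitted
    nswap = 0
    for t in range(e1.shape[0]):
        i = e1[t]
        j = e2[t]
        if i == j:
            continue
        a = edges[i, 0]
        b = edges[i, 1]
        u = edges[j, 0]
        v = edges[j, 1]
        if side[t] == 1:
            c, d = v, u
        else:
            c, d = u, v
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[i, 0] = a
        edges[i, 1] = d
        edges[j, 0] = c
        edges[j, 1] = b
        nswap += 1
    return nswap


try:  # numba speeds up the swap loop ~100x; plain Python is the fallback
    from numba import njit

    _rewire_kernel_fast = njit(cache=False)(_rewire_kernel)
except Exception:  # pragma: no cover
    _rewire_kernel_fast = _rewire_kernel


def random_reference(
    A: np.ndarray,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
) -> np.ndarray:
    """Degree-preserving randomization by Maslov-Sneppen double-edge swaps.

    Attempts ``swaps_per_edge * |E|`` swaps, each replacing edges (a,b),
    (c,d) by (a,d), (c,b) when the result stays a simple graph.  The
    degree sequence is preserved exactly.  A pure function of the seed.
    Graphs admitting no valid swap are returned unchanged with a warning.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A = np.ascontiguousarray(np.asarray(A, dtype=np.uint8))
    iu, ju = np.triu_indices(A.shape[0], k=1)
    keep = A[iu, ju] == 1
    edges = np.column_stack([iu[keep], ju[keep]]).astype(np.int64)
    m = edges.shape[0]
    if m < 2:
        warnings.warn("graph has fewer than 2 edges; returned unchanged")
        return A.copy()
    attempts = int(swaps_per_edge) * m
    e1 = rng.integers(0, m, size=attempts)
    e2 = rng.integers(0, m, size=attempts)
    side = rng.integers(0, 2, size=attempts).astype(np.int64)
    out = A.copy()
    nswap = _rewire_kernel_fast(out, edges, e1, e2, side)
    if nswap == 0:
        warnings.warn("no valid double-edge swap exists; graph returned unchanged")
    return out


# ---------------------------------------------------------------------------
# normalized global metrics

@dataclass(frozen=True)
class SmallWorldResult:
    clustering: float
    path_length: float
    clustering_null: float
    path_length_null: float
    gamma: float
    lam: float
    sigma: float


def normalized_global_metrics(
    A: np.ndarray,
    n_null: int = 100,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
    path_policy: str = "reachable",
    null_graphs: list[np.ndarray] | None = None,
) -> SmallWorldResult:
    """Small-world normalization of clustering and path length.

    ``null_graphs`` overrides null generation (used for self-normalization
    checks); otherwise ``n_null`` Maslov-Sneppen references are generated
    from the seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    _, C = clustering_coefficient(A)
    L = characteristic_path_length(A, policy=path_policy)
    if null_graphs is None:
        if n_null < 1:
            raise ValueError("n_null must be >= 1")
        null_graphs = [
            random_reference(A, seed=rng, swaps_per_edge=swaps_per_edge)
            for _ in range(n_null)
        ]
    c_null = float(np.mean([clustering_coefficient(R)[1] for R in null_graphs]))
    l_null = float(
        np.mean([characteristic_path_length(R, policy=path_policy) for R in null_graphs])
    )
    if c_null == 0 or l_null == 0:
        raise ValueError("null-model mean metric is zero; normalization undefined")
    gamma = C / c_null
    lam = L / l_null
    return SmallWorldResult(
        clustering=C,
        path_length=L,
        clustering_null=c_null,
        path_length_null=l_null,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
    )


# ---------------------------------------------------------------------------
# density profiles and AUC

def auc_over_densities(values: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal integral of a metric profile against density."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.shape[-1] != grid.shape[0]:
        raise ValueError(
            f"length mismatch: {values.shape[-1]} values vs {grid.shape[0]} densities"
        )
    if grid.shape[0] < 2:
        raise ValueError("need at least 2 grid points for AUC")
    return np.trapezoid(values, grid, axis=-1)


@dataclass(frozen=True)
class GlobalMetricsProfile:
    """gamma/lambda/sigma across the density grid, plus AUC summaries."""

    densities: np.ndarray
    clustering: np.ndarray
    path_length: np.ndarray
    clustering_null: np.ndarray
    path_length_null: np.ndarray
    gamma: np.ndarray
    lam: np.ndarray
    sigma: np.ndarray

    @property
    def auc(self) -> dict[str, float]:
        return {
            "gamma": float(auc_over_densities(self.gamma, self.densities)),
            "lambda": float(auc_over_densities(self.lam, self.densities)),
            "sigma": float(auc_over_densities(self.sigma, self.densities)),
        }


@dataclass(frozen=True)
class LocalMetricsProfile:
    """Nodal clustering, local efficiency and degree across densities."""

    densities: np.ndarray
    clustering: np.ndarray  # (n_nodes, n_densities)
    local_efficiency: np.ndarray
    degree: np.ndarray

    @property
    def auc(self) -> dict[str, np.ndarray]:
        return {
            "clustering": auc_over_densities(self.clustering, self.densities),
            "local_efficiency": auc_over_densities(self.local_efficiency, self.densities),
            "degree": auc_over_densities(self.degree.astype(float), self.densities),
        }


def metric_profiles(
    W: np.ndarray,
    grid: np.ndarray,
    n_null: int = 100,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: int = 10,
    path_policy: str = "reachable",
) -> tuple[GlobalMetricsProfile, LocalMetricsProfile]:
    """Threshold a weight matrix at each density and evaluate all metrics."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = np.asarray(grid, dtype=float)
    n = W.shape[0]
    K = grid.shape[0]
    g = {k: np.empty(K) for k in ("C", "L", "Cn", "Ln", "gamma", "lam", "sigma")}
    loc_c = np.empty((n, K))
    loc_e = np.empty((n, K))
    loc_k = np.empty((n, K), dtype=np.int64)
    for t, d in enumerate(grid):
        A = threshold_at_density(W, d)
        res = normalized_global_metrics(
            A, n_null=n_null, seed=rng, swaps_per_edge=swaps_per_edge,
            path_policy=path_policy,
        )
        g["C"][t] = res.clustering
        g["L"][t] = res.path_length
        g["Cn"][t] = res.clustering_null
        g["Ln"][t] = res.path_length_null
        g["gamma"][t] = res.gamma
        g["lam"][t] = res.lam
        g["sigma"][t] = res.sigma
        loc_c[:, t] = clustering_coefficient(A)[0]
        loc_e[:, t] = local_efficiency(A)
        loc_k[:, t] = nodal_degree(A)
    gp = GlobalMetricsProfile(
        densities=grid,
        clustering=g["C"],
        path_length=g["L"],
        clustering_null=g["Cn"],
        path_length_null=g["Ln"],
        gamma=g["gamma"],
        lam=g["lam"],
        sigma=g["sigma"],
    )
    lp = LocalMetricsProfile(
        densities=grid, clustering=loc_c, local_efficiency=loc_e, degree=loc_k
    )
    return gp, lp
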