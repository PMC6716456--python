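"""Weighted-directed graph measures of segregation and integration.

Networks are built from the absolute value of connectivity, max-normalized
so weights lie in [0, 1].  Segregation: transitivity (global), clustering
coefficient and local efficiency (nodal), in the Fagiolo cube-root
triangle-intensity formulations for weighted digraphs.  Integration:
global efficiency (global), shortest path length and edge betweenness
(connection-level), on edge lengths 1/weight.

Edge betweenness here counts *all* shortest directed paths through an
edge, ties included, summed over ordered source-target pairs (raw counts,
not fractional Brandes shares).

Dynamic-connectivity tensors are treated as a sequence of snapshot
graphs; each measure's snapshot trajectory is reduced to its variance,
giving the temporal-variability ("flexibility") flavor of every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

_REL_TOL = 1e-9


@dataclass
class WeightedDigraph:
    W: np.ndarray                     # (k, k) weights in [0, 1], zero diagonal
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")
        if not self.labels:
            self.labels = [f"R{i:02d}" for i in range(self.W.shape[0])]

    @property
    def k(self) -> int:
        return self.W.shape[0]


@dataclass
class MetricSet:
    transitivity: float
    global_efficiency: float
    cc: np.ndarray                    # (k,)
    eff_loc: np.ndarray               # (k,)
    spl: np.ndarray                   # (k, k) ordered-pair distances (+inf unreachable)
    eb: np.ndarray                    # (k, k) shortest-path counts per edge


# MetricVarianceSet has the same slots, holding variances over snapshots
MetricVarianceSet = MetricSet


def to_graph(conn_matrix: np.ndarray, labels: list[str] | None = None) -> WeightedDigraph:
    """|connectivity|, zero diagonal, scaled so max weight is 1."""
    W = np.abs(np.asarray(conn_matrix, dtype=float))
    if W.shape[0] != W.shape[1]:
        raise ValueError("connectivity matrix must be square")
    np.fill_diagonal(W, 0.0)
    m = W.max()
    if m > 0:
        W = W / m
    return WeightedDigraph(W=W, labels=labels or [])


def _lengths(g: WeightedDigraph) -> np.ndarray:
    with np.errstate(divide="ignore"):
        L = np.where(g.W > 0, 1.0 / g.W, np.inf)
    np.fill_diagonal(L, np.inf)  # no self loops
    return L


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

def _triangle_terms(g: WeightedDigraph) -> tuple[np.ndarray, np.ndarray]:
    """Cube-root triangle intensity per node and the possible-triangle count."""
    W = g.W
    A = (W > 0).astype(float)
    S = np.cbrt(W) + np.cbrt(W.T)
    cyc3 = np.diag(S @ S @ S) / 2.0
    K = A.sum(axis=0) + A.sum(axis=1)              # total (in+out) degree
    denom = K * (K - 1) - 2.0 * np.diag(A @ A)     # minus reciprocal pairs
    return cyc3, denom


def transitivity(g: WeightedDigraph) -> float:
    """Global triangle intensity; NaN sentinel when k < 3 (undefined)."""
    if g.k < 3:
        return float("nan")
    cyc3, denom = _triangle_terms(g)
    total = denom.sum()
    return float(cyc3.sum() / total) if total > 0 else 0.0


def clustering_coefficient(g: WeightedDigraph) -> np.ndarray:
    cyc3, denom = _triangle_terms(g)
    out = np.zeros(g.k)
    ok = denom > 0
    out[ok] = cyc3[ok] / denom[ok]
    return out


def local_efficiency(g: WeightedDigraph) -> np.ndarray:
    """Efficiency of each node's neighborhood subgraph (weighted-directed).

    For node u with neighbors V: cube-root products of u's connections to
    j, h in V with the symmetrized inverse distance between j and h inside
    the subgraph induced by V, normalized by the possible neighbor pairs.
    """
    W, k = g.W, g.k
    A = (W > 0)
    L = _lengths(g)
    out = np.zeros(k)
    for u in range(k):
        V = np.flatnonzero(A[u, :] | A[:, u])
        if V.size < 2:
            continue
        sub = L[np.ix_(V, V)]
        D = _dijkstra(sub)
        with np.errstate(divide="ignore"):
            e = np.where(D > 0, 1.0 / D, 0.0)
        np.fill_diagonal(e, 0.0)
        se = np.cbrt(e) + np.cbrt(e.T)
        sw = np.cbrt(W[u, V]) + np.cbrt(W[V, u])
        numer = float((np.outer(sw, sw) * se).sum()) / 2.0
        if numer <= 0:
            continue
        sa = A[u, V].astype(float) + A[V, u].astype(float)
        denom = sa.sum() ** 2 - (sa ** 2).sum()
        if denom > 0:
            out[u] = numer / denom
    return out


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _dijkstra(L: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths for a dense length matrix (inf = absent)."""
    graph = np.where(np.isinf(L), 0.0, L)
    return dijkstra(csr_array(graph), directed=True)


def distance_matrix(g: WeightedDigraph) -> np.ndarray:
    """Shortest directed path lengths under edge length 1/weight."""
    return _dijkstra(_lengths(g))


def global_efficiency(g: WeightedDigraph) -> float:
    """Mean over ordered pairs of inverse distance (unreachable -> 0)."""
    if g.k < 2:
        return 0.0
    D = distance_matrix(g)
    off = ~np.eye(g.k, dtype=bool)
    inv = np.zeros_like(D)
    ok = np.isfinite(D) & (D > 0)
    inv[ok] = 1.0 / D[ok]
    return float(inv[off].sum() / (g.k * (g.k - 1)))


def _path_counts(L: np.ndarray, D: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of distinct shortest directed paths s -> t."""
    k = L.shape[0]
    sigma = np.zeros((k, k))
    for s in range(k):
        order = np.argsort(D[s], kind="stable")
        sigma[s, s] = 1.0
        for v in order:
            if v == s or np.isinf(D[s, v]):
                continue
            tol = _REL_TOL * max(1.0, D[s, v])
            preds = np.flatnonzero(np.abs(D[s, :] + L[:, v] - D[s, v]) <= tol)
            sigma[s, v] = sigma[s, preds].sum()
    return sigma


def edge_betweenness(g: WeightedDigraph) -> np.ndarray:
    """eb[u, v] = total count of shortest directed paths traversing (u, v).

    Summed over all ordered source-target pairs, with tied shortest paths
    all counted; absent edges score 0.
    """
    L = _lengths(g)
    D = _dijkstra(L)
    sigma = _path_counts(L, D)
    k = g.k
    eb = np.zeros((k, k))
    finite = np.isfinite(D)
    offdiag = ~np.eye(k, dtype=bool)
    valid_st = finite & offdiag
    for u in range(k):
        for v in range(k):
            if u == v or np.isinf(L[u, v]):
                continue
            total = D[:, u][:, None] + L[u, v] + D[v, :][None, :]
            tol = _REL_TOL * np.maximum(1.0, np.where(finite, D, 1.0))
            on_path = valid_st & (total <= D + tol)
            if on_path.any():
                counts = sigma[:, u][:, None] * sigma[v, :][None, :]
                eb[u, v] = float(counts[on_path].sum())
    return eb


# ---------------------------------------------------------------------------
# Composite metric sets
# ---------------------------------------------------------------------------

def static_metrics(conn_matrix: np.ndarray, labels: list[str] | None = None) -> MetricSet:
    """All six measures on the graph built from a connectivity matrix."""
    g = to_graph(np.asarray(conn_matrix, dtype=float), labels)
    return MetricSet(
        transitivity=transitivity(g),
        global_efficiency=global_efficiency(g),
        cc=clustering_coefficient(g),
        eff_loc=local_efficiency(g),
        spl=distance_matrix(g),
        eb=edge_betweenness(g),
    )


def dynamic_metric_variance(dgc: np.ndarray, burn_in: int = 0, stride: int = 1,
                            labels: list[str] | None = None) -> MetricVarianceSet:
    """Variance over snapshot time of every measure on |DGC(t)| graphs.

    ``dgc`` is a (T, k, k) tensor; snapshots t = burn_in, burn_in+stride,
    ... are each turned into a graph and measured; at least 30 snapshots
    are required.  All-zero snapshots yield zero metrics (not an error).
    """
    T = dgc.shape[0]
    ts_idx = range(burn_in, T, stride)
    n = len(ts_idx)
    if n < 30:
        raise ValueError(f"need >= 30 snapshots, got {n}")
    k = dgc.shape[1]
    tr_ = np.empty(n)
    ge = np.empty(n)
    cc = np.empty((n, k))
    el = np.empty((n, k))
    spl = np.empty((n, k, k))
    eb = np.empty((n, k, k))
    for m, t in enumerate(ts_idx):
        ms = static_metrics(dgc[t], labels)
        tr_[m], ge[m], cc[m], el[m], spl[m], eb[m] = (
            ms.transitivity, ms.global_efficiency, ms.cc, ms.eff_loc, ms.spl, ms.eb)
    return MetricVarianceSet(
        transitivity=float(np.var(tr_)),
        global_efficiency=float(np.var(ge)),
        cc=np.var(cc, axis=0),
        eff_loc=np.var(el, axis=0),
        spl=np.var(spl, axis=0),
        eb=np.var(eb, axis=0),
    )
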