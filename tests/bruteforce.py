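"""Independent brute-force oracles used to cross-check the fast implementations.

Everything here is written as plain loops / exhaustive enumeration and
deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = float("inf")


# ---------------------------------------------------------------------------
# Shortest paths by exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def all_simple_paths(L: np.ndarray, s: int, t: int):
    """Yield every simple directed path s -> t with its total length."""
    k = L.shape[0]

    def extend(path, length):
        last = path[-1]
        if last == t and len(path) > 1:
            yield list(path), length
            return
        for nxt in range(k):
            if nxt in path or math.isinf(L[last, nxt]):
                continue
            yield from extend(path + [nxt], length + L[last, nxt])

    yield from extend([s], 0.0)


def brute_distances(L: np.ndarray) -> np.ndarray:
    k = L.shape[0]
    D = np.full((k, k), INF)
    np.fill_diagonal(D, 0.0)
    for s in range(k):
        for t in range(k):
            if s == t:
                continue
            best = INF
            for _, length in all_simple_paths(L, s, t):
                best = min(best, length)
            D[s, t] = best
    return D


def brute_edge_betweenness(L: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Count every tied shortest path through each edge, over ordered pairs."""
    k = L.shape[0]
    D = brute_distances(L)
    eb = np.zeros((k, k))
    for s in range(k):
        for t in range(k):
            if s == t or math.isinf(D[s, t]):
                continue
            for path, length in all_simple_paths(L, s, t):
                if length <= D[s, t] * (1 + tol) + tol:
                    for u, v in zip(path[:-1], path[1:]):
                        eb[u, v] += 1
    return eb


def brute_global_efficiency(L: np.ndarray) -> float:
    D = brute_distances(L)
    k = L.shape[0]
    total = 0.0
    for i in range(k):
        for j in range(k):
            if i != j and not math.isinf(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (k * (k - 1))


# ---------------------------------------------------------------------------
# Triangle measures by direct enumeration
# ---------------------------------------------------------------------------

def brute_clustering(W: np.ndarray) -> np.ndarray:
    """Fagiolo weighted-directed clustering coefficient via triple loops."""
    k = W.shape[0]
    A = (W > 0).astype(float)
    cr = np.cbrt(W)
    out = np.zeros(k)
    for i in range(k):
        t_i = 0.0
        for j in range(k):
            for h in range(k):
                if j == i or h == i:
                    continue
                t_i += (cr[i, j] + cr[j, i]) * (cr[i, h] + cr[h, i]) * (cr[j, h] + cr[h, j])
        t_i /= 2.0
        deg = A[i, :].sum() + A[:, i].sum()
        recip = float((A[i, :] * A[:, i]).sum())
        denom = deg * (deg - 1) - 2 * recip
        out[i] = t_i / denom if denom > 0 else 0.0
    return out


def brute_transitivity(W: np.ndarray) -> float:
    k = W.shape[0]
    A = (W > 0).astype(float)
    cr = np.cbrt(W)
    num = 0.0
    den = 0.0
    for i in range(k):
        t_i = 0.0
        for j in range(k):
            for h in range(k):
                if j == i or h == i:
                    continue
                t_i += (cr[i, j] + cr[j, i]) * (cr[i, h] + cr[h, i]) * (cr[j, h] + cr[h, j])
        num += t_i / 2.0
        deg = A[i, :].sum() + A[:, i].sum()
        recip = float((A[i, :] * A[:, i]).sum())
        den += deg * (deg - 1) - 2 * recip
    return num / den if den > 0 else 0.0


def brute_local_efficiency(W: np.ndarray) -> np.ndarray:
    """Neighborhood-subgraph efficiency with brute-force distances."""
    k = W.shape[0]
    A = W > 0
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, INF)
    np.fill_diagonal(L, INF)
    out = np.zeros(k)
    for u in range(k):
        V = [v for v in range(k) if A[u, v] or A[v, u]]
        if len(V) < 2:
            continue
        sub = L[np.ix_(V, V)]
        D = brute_distances(sub)
        numer = 0.0
        for a, j in enumerate(V):
            for b, h in enumerate(V):
                if a == b:
                    continue
                e_ab = 1.0 / D[a, b] if (not math.isinf(D[a, b]) and D[a, b] > 0) else 0.0
                e_ba = 1.0 / D[b, a] if (not math.isinf(D[b, a]) and D[b, a] > 0) else 0.0
                sw = (np.cbrt(W[u, j]) + np.cbrt(W[j, u])) * (np.cbrt(W[u, h]) + np.cbrt(W[h, u]))
                numer += sw * (np.cbrt(e_ab) + np.cbrt(e_ba)) / 2.0
        sa = [float(A[u, v]) + float(A[v, u]) for v in V]
        denom = sum(sa) ** 2 - sum(x * x for x in sa)
        if numer > 0 and denom > 0:
            out[u] = numer / denom
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg by definition (O(m^2))
# ---------------------------------------------------------------------------

def brute_bh(pvals, q=0.05):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= q * rank / m:
            k_star = rank
    mask = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            mask[idx] = True
    return np.array(mask)


# ---------------------------------------------------------------------------
# Binomial tail by direct summation
# ---------------------------------------------------------------------------

def brute_binom_tail(n_correct: int, n_total: int, p: float) -> float:
    total = 0.0
    for x in range(n_correct, n_total + 1):
        total += math.comb(n_total, x) * p**x * (1 - p) ** (n_total - x)
    return total
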