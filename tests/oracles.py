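"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive path enumeration,
subset enumeration, dense linear algebra, literal sort-based medians —
and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def bf_degree(g: nx.Graph) -> dict:
    return {v: sum(1 for u in g.nodes if g.has_edge(v, u) and u != v) for v in g.nodes}


def _all_simple_paths(g: nx.Graph, s, t):
    """Yield every simple s-t path by explicit DFS."""
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nbr in g.neighbors(node):
            if nbr not in path:
                stack.append((nbr, path + [nbr]))


def bf_shortest_path_profile(g: nx.Graph, s, t):
    """(shortest length, count, per-node interior pass counts) or None."""
    best = None
    count = 0
    interior: dict = {}
    for path in _all_simple_paths(g, s, t):
        d = len(path) - 1
        if best is None or d < best:
            best, count, interior = d, 1, {}
            for v in path[1:-1]:
                interior[v] = interior.get(v, 0) + 1
        elif d == best:
            count += 1
            for v in path[1:-1]:
                interior[v] = interior.get(v, 0) + 1
    if best is None:
        return None
    return best, count, interior


def bf_betweenness(g: nx.Graph) -> dict:
    """Unnormalised betweenness over unordered pairs, by path enumeration."""
    bc = {v: 0.0 for v in g.nodes}
    for s, t in itertools.combinations(g.nodes, 2):
        prof = bf_shortest_path_profile(g, s, t)
        if prof is None:
            continue
        _, sigma, interior = prof
        for v, sigma_v in interior.items():
            bc[v] += sigma_v / sigma
    return bc


def bf_closeness(g: nx.Graph) -> dict:
    """Per-component closeness from enumerated shortest-path lengths."""
    cc = {}
    for v in g.nodes:
        dists = []
        for u in g.nodes:
            if u == v:
                continue
            prof = bf_shortest_path_profile(g, v, u)
            if prof is not None:
                dists.append(prof[0])
        cc[v] = len(dists) / sum(dists) if dists else 0.0
    return cc


def bf_principal_eigen(g: nx.Graph):
    """(lambda_max, full spectrum gap) via dense symmetric eigendecomposition."""
    nodes = list(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    vals = np.linalg.eigvalsh(a)
    gap = vals[-1] - vals[-2] if len(vals) > 1 else np.inf
    return float(vals[-1]), float(gap), nodes, a


def check_eigenvector(g: nx.Graph, ec: dict, atol: float = 1e-8) -> None:
    """Assert ec is a non-negative unit eigenvector of the top eigenvalue."""
    lam, _, nodes, a = bf_principal_eigen(g)
    v = np.array([ec[n] for n in nodes])
    assert np.all(v >= -atol)
    assert abs(np.linalg.norm(v) - 1.0) < atol
    assert np.max(np.abs(a @ v - lam * v)) < max(atol, 1e-6)


def bf_lac(g: nx.Graph) -> dict:
    out = {}
    for v in g.nodes:
        nbrs = [u for u in g.nodes if g.has_edge(v, u) and u != v]
        if not nbrs:
            out[v] = 0.0
            continue
        induced = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b)
        )
        out[v] = 2.0 * induced / len(nbrs)
    return out


def bf_nc(g: nx.Graph, degenerate_value: float = 0.0) -> dict:
    deg = bf_degree(g)
    out = {}
    for v in g.nodes:
        total = 0.0
        for w in g.nodes:
            if not g.has_edge(v, w) or w == v:
                continue
            z = sum(
                1
                for x in g.nodes
                if x not in (v, w) and g.has_edge(v, x) and g.has_edge(w, x)
            )
            denom = min(deg[v] - 1, deg[w] - 1)
            total += z / denom if denom > 0 else degenerate_value
        out[v] = total
    return out


def bf_maximal_cliques(g: nx.Graph):
    """All maximal cliques of size >= 2 by explicit subset enumeration."""
    nodes = list(g.nodes)
    cliques = [
        set(sub)
        for r in range(2, len(nodes) + 1)
        for sub in itertools.combinations(nodes, r)
        if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2))
    ]
    return [c for c in cliques if not any(c < d for d in cliques)]


def bf_mcc(g: nx.Graph) -> dict:
    scores = {v: 0 for v in g.nodes}
    for clique in bf_maximal_cliques(g):
        contrib = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += contrib
    return scores


def bf_median(values) -> float:
    """Sort-based median: middle element, or mean of the two middle ones."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return float(s[mid]) if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def bf_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total if total else 1.0


def bf_hypergeom_pmf_table(K: int, n: int, N: int) -> dict[int, float]:
    """Counts of overlap k over all C(N, n) draws, as probabilities."""
    counts: dict[int, int] = {}
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        k = sum(1 for x in draw if x < K)
        counts[k] = counts.get(k, 0) + 1
    return {k: c / total for k, c in counts.items()}


def bf_bh(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up rule, computed literally."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, m * pvalues[i] / rank_from_top)
        q[i] = min(val, 1.0)
        prev = val
    return q
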