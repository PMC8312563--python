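"""Brute-force reference implementations used as independent oracles.

Pure-Python, loop-based, written directly from the metric definitions;
intentionally independent of the vectorized/library-backed code paths in
wmnet.  Only feasible for small graphs (n <= ~10).
"""

from __future__ import annotations

import math

INF = math.inf


def floyd_warshall(adj) -> list[list[float]]:
    n = len(adj)
    d = [[0.0 if i == j else (1.0 if adj[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def clustering_coefficients(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        k = len(nbrs)
        if k < 2:
            out.append(0.0)
            continue
        links = sum(
            1 for a in range(k) for b in range(a + 1, k) if adj[nbrs[a]][nbrs[b]]
        )
        out.append(2.0 * links / (k * (k - 1)))
    return out


def global_efficiency(adj) -> float:
    d = floyd_warshall(adj)
    n = len(adj)
    if n < 2:
        return 0.0
    total = sum(
        (1.0 / d[i][j] if d[i][j] != INF else 0.0)
        for i in range(n)
        for j in range(n)
        if i != j
    )
    return total / (n * (n - 1))


def nodal_efficiency(adj) -> list[float]:
    d = floyd_warshall(adj)
    n = len(adj)
    return [
        sum((1.0 / d[i][j] if d[i][j] != INF else 0.0) for j in range(n) if j != i)
        / (n - 1)
        for i in range(n)
    ]


def local_efficiency(adj) -> list[float]:
    n = len(adj)
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i][j]]
        if len(nbrs) < 2:
            out.append(0.0)
            continue
        sub = [[adj[a][b] for b in nbrs] for a in nbrs]
        out.append(global_efficiency(sub))
    return out


def characteristic_path_length(adj) -> float:
    d = floyd_warshall(adj)
    n = len(adj)
    finite = [d[i][j] for i in range(n) for j in range(n) if i != j and d[i][j] != INF]
    return sum(finite) / len(finite) if finite else math.nan


def _all_simple_paths(adj, s, t, max_len=None):
    n = len(adj)
    paths = []
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            paths.append(path)
            continue
        if max_len is not None and len(path) > max_len:
            continue
        for w in range(n):
            if adj[v][w] and w not in path:
                stack.append((w, path + [w]))
    return paths


def betweenness(adj) -> list[float]:
    """Exhaustive geodesic enumeration; each unordered pair counted once,
    endpoints excluded, fractional credit per geodesic."""
    n = len(adj)
    d = floyd_warshall(adj)
    bet = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            if d[s][t] == INF:
                continue
            hops = int(d[s][t])
            geos = [
                p for p in _all_simple_paths(adj, s, t, max_len=hops) if len(p) == hops + 1
            ]
            for p in geos:
                for v in p[1:-1]:
                    bet[v] += 1.0 / len(geos)
    return bet
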