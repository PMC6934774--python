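"""Brute-force oracles for nodal graph metrics on tiny graphs.

Everything here works by explicit enumeration (simple-path DFS, triple
loops) and is deliberately independent of the package implementation. Only
usable for graphs with at most ~8 nodes.
"""

from __future__ import annotations

import numpy as np


def strength_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += w[i, j]
    return out


def degree_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if w[i, j] > 0:
                out[i] += 1
    return out


def _simple_path_scan(w: np.ndarray, source: int):
    """DFS over all simple paths from ``source``, summing lengths 1/w
    left-to-right (the same association order a Dijkstra relaxation uses).

    Yields (target, length, interior_nodes_tuple) for every simple path.
    """
    n = w.shape[0]
    visited = [False] * n
    visited[source] = True
    path = [source]

    def rec(v, length):
        for u in range(n):
            if w[v, u] > 0 and not visited[u]:
                new_len = length + 1.0 / w[v, u]
                yield u, new_len, tuple(path[1:])
                visited[u] = True
                path.append(u)
                yield from rec(u, new_len)
                path.pop()
                visited[u] = False

    yield from rec(source, 0.0)


def apsp_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances by exhaustive path enumeration."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t, length, _ in _simple_path_scan(w, s):
            if length < d[s, t]:
                d[s, t] = length
    return d


def local_efficiency_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = apsp_oracle(sub)
        total = 0.0
        pairs = 0
        for a in range(len(nbrs)):
            for b in range(len(nbrs)):
                if a == b:
                    continue
                pairs += 1
                if np.isfinite(d[a, b]):
                    total += 1.0 / d[a, b]
        out[i] = total / pairs
    return out


def clustering_oracle(w: np.ndarray) -> np.ndarray:
    """Barrat weighted clustering by triple-loop triangle enumeration."""
    n = w.shape[0]
    a = (w > 0).astype(int)
    out = np.zeros(n)
    for i in range(n):
        deg = a[i].sum()
        s = w[i].sum()
        if deg < 2 or s == 0:
            continue
        acc = 0.0
        for j in range(n):
            for k in range(n):
                if a[i, j] and a[i, k] and a[j, k]:
                    acc += (w[i, j] + w[i, k]) / 2.0
        out[i] = acc / (s * (deg - 1))
    return out


def betweenness_oracle(w: np.ndarray, normalized: bool = True) -> np.ndarray:
    """Exhaustive shortest-path betweenness with tied-path multiplicity.

    For every ordered (s, t) pair, enumerates all simple paths, keeps those
    whose left-to-right length sum equals the minimum exactly, and credits
    each interior node with (paths through v) / (all shortest paths). The
    two orientations of each unordered pair are averaged, mirroring an
    undirected Brandes accumulation.
    """
    n = w.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        best = np.full(n, np.inf)
        count = np.zeros(n)
        through = np.zeros((n, n))  # through[t, v]
        for t, length, interior in _simple_path_scan(w, s):
            if length < best[t]:
                best[t] = length
                count[t] = 1.0
                through[t] = 0.0
                for v in interior:
                    through[t, v] = 1.0
            elif length == best[t]:
                count[t] += 1.0
                for v in interior:
                    through[t, v] += 1.0
        for t in range(n):
            if t == s or count[t] == 0:
                continue
            bc += through[t] / count[t]
    bc /= 2.0
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


def random_weighted_graph(
    rng: np.random.Generator, n: int, density: float
) -> np.ndarray:
    """Random symmetric weighted graph with weights in (0, 1)."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.05, 1.0)
    return w
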