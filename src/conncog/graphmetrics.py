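"""Nodal metrics on weighted undirected networks.

Five node-based measures on FA-weighted connectomes: strength, degree,
local efficiency, (Barrat) weighted clustering and weighted betweenness
centrality. Shortest paths use the reciprocal-weight length convention
(length = 1/FA), the dominant choice for FA-weighted structural networks:
strong connections are short. The -log(w) alternative is available through
``weight_to_length``.

Nodes with fewer than two neighbours have local efficiency and clustering
defined as 0 (not NaN) so that downstream group statistics never see missing
values.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connprep import EdgeMask, apply_mask
from .synthcohort import ConnectivityMatrix

__all__ = [
    "NodeMetricTable",
    "METRICS",
    "weight_to_length",
    "node_strength",
    "node_degree",
    "shortest_path_lengths",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness_centrality",
    "compute_metric",
    "compute_all_metrics",
]

METRICS = (
    "strength",
    "local_efficiency",
    "clustering",
    "betweenness",
    "degree",
)


@dataclass
class NodeMetricTable:
    """Values of one nodal metric for every subject (subjects x nodes)."""

    metric_name: str
    node_labels: list[str]
    values: pd.DataFrame  # index: subject_id, columns: node labels

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.values.to_csv(fh, index_label="subject_id")

    @classmethod
    def from_csv(cls, path, metric_name: str) -> "NodeMetricTable":
        df = pd.read_csv(path, comment="#", index_col="subject_id")
        return cls(metric_name, [str(c) for c in df.columns], df)


def _as_weights(matrix) -> np.ndarray:
    if isinstance(matrix, ConnectivityMatrix):
        return np.asarray(matrix.weights, dtype=float)
    return np.asarray(matrix, dtype=float)


def weight_to_length(weights: np.ndarray, convention: str = "inverse") -> np.ndarray:
    """Map connection weights to path lengths; absent edges become inf."""
    w = np.asarray(weights, dtype=float)
    lengths = np.full_like(w, np.inf)
    pos = w > 0
    if convention == "inverse":
        lengths[pos] = 1.0 / w[pos]
    elif convention == "neglog":
        lengths[pos] = -np.log(w[pos])
    else:
        raise ValueError(f"unknown length convention '{convention}'")
    return lengths


def node_strength(matrix) -> np.ndarray:
    """s_i = sum of weights of all edges incident to node i."""
    return _as_weights(matrix).sum(axis=1)


def node_degree(matrix) -> np.ndarray:
    """d_i = number of edges incident to node i."""
    return (_as_weights(matrix) > 0).sum(axis=1)


def shortest_path_lengths(matrix, convention: str = "inverse") -> np.ndarray:
    """All-pairs shortest-path distances under the chosen length convention.

    Disconnected pairs get inf; the diagonal is 0.
    """
    w = _as_weights(matrix)
    lengths = weight_to_length(w, convention)
    graph = np.where(np.isinf(lengths), 0.0, lengths)
    d = _csgraph_shortest_path(graph, method="D", directed=False)
    return d


def _floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs distances from a length matrix (inf = absent), in place."""
    d = lengths.copy()
    np.fill_diagonal(d, 0.0)
    for k in range(d.shape[0]):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def local_efficiency(matrix, convention: str = "inverse") -> np.ndarray:
    """Mean inverse shortest-path length among each node's neighbours.

    For node i with neighbour set N_i (|N_i| >= 2): the subgraph induced by
    N_i keeps the original weights; E_loc(i) is the mean over ordered pairs
    (j != k) in N_i of 1/d_jk within that subgraph (1/inf = 0). Nodes with
    fewer than two neighbours get 0.
    """
    w = _as_weights(matrix)
    n = w.shape[0]
    lengths = weight_to_length(w, convention)
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        k = nbrs.size
        if k < 2:
            continue
        d = _floyd_warshall(lengths[np.ix_(nbrs, nbrs)])
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        eff[i] = inv.sum() / (k * (k - 1))
    return eff


def clustering_coefficient(matrix) -> np.ndarray:
    """Barrat weighted clustering coefficient.

    C_i = 1 / (s_i (d_i - 1)) * sum_{j,k} ((w_ij + w_ik)/2) a_ij a_ik a_jk,
    with a the binary adjacency; nodes with degree < 2 get 0.
    """
    w = _as_weights(matrix)
    a = (w > 0).astype(float)
    s = w.sum(axis=1)
    d = a.sum(axis=1)
    # sum_{j,k} (w_ij+w_ik)/2 a_ij a_ik a_jk  ==  sum_j w_ij a_ij (A@A)_ij
    common = a @ a
    tri = ((w * a) * common).sum(axis=1)
    out = np.zeros(w.shape[0])
    ok = (d >= 2) & (s > 0)
    out[ok] = tri[ok] / (s[ok] * (d[ok] - 1.0))
    return out


def betweenness_centrality(
    matrix, normalized: bool = True, convention: str = "inverse"
) -> np.ndarray:
    """Weighted betweenness via Brandes' algorithm with exact path counting.

    Edge lengths follow the weight-to-length convention; shortest-path
    multiplicity is accumulated exactly. For undirected graphs the raw value
    is halved and, when ``normalized``, divided by (n-1)(n-2)/2.
    """
    w = _as_weights(matrix)
    n = w.shape[0]
    if n < 3:
        return np.zeros(n)
    lengths = weight_to_length(w, convention)
    nbrs = [np.flatnonzero(w[i] > 0) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            dv, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u in nbrs[v]:
                if done[u]:
                    continue
                nd = dv + lengths[v, u]
                if nd < dist[u]:
                    dist[u] = nd
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (nd, u))
                elif nd == dist[u]:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    bc /= 2.0  # each unordered pair counted from both endpoints
    if normalized:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


_DISPATCH = {
    "strength": node_strength,
    "degree": node_degree,
    "local_efficiency": local_efficiency,
    "clustering": clustering_coefficient,
    "betweenness": betweenness_centrality,
}


def compute_metric(
    matrices: Sequence[ConnectivityMatrix],
    metric_name: str,
    mask: EdgeMask | None = None,
) -> NodeMetricTable:
    """One metric for every subject; optionally applies an edge mask first."""
    if metric_name not in _DISPATCH:
        raise ValueError(f"unknown metric '{metric_name}'")
    fn = _DISPATCH[metric_name]
    labels = matrices[0].node_labels
    rows, ids = [], []
    for mat in matrices:
        if mask is not None:
            mat = apply_mask(mat, mask)
        try:
            mat.validate()
        except ValueError as exc:
            raise ValueError(f"subject {mat.subject_id}: {exc}") from exc
        rows.append(fn(mat.weights))
        ids.append(mat.subject_id)
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=labels)
    return NodeMetricTable(metric_name, list(labels), df)


def compute_all_metrics(
    matrices: Sequence[ConnectivityMatrix],
    mask: EdgeMask | None = None,
    metrics: Sequence[str] = METRICS,
) -> dict[str, NodeMetricTable]:
    """All requested nodal metric tables, rows aligned to subject order."""
    return {name: compute_metric(matrices, name, mask) for name in metrics}
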