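"""Weighted graph-theory measures of a connectivity matrix.

Five global measures (characteristic path length, global efficiency,
transitivity, modularity, density) and four node-level measures (clustering
coefficient, local efficiency, betweenness centrality, degree centrality).

Conventions, fixed once for the whole package:

* path-based measures traverse edge *lengths* ``1/weight`` (stronger
  connection = shorter path); a zero weight means "no edge";
* clustering and transitivity use the geometric-mean (Onnela) triangle
  intensity on max-normalized weights, with binary degrees, so they reduce
  to the classical quantities on 0/1 graphs;
* degree centrality is the node strength (sum of incident weights) —
  counting links on a complete weighted graph is constant and carries no
  information;
* betweenness is normalized by (n-1)(n-2) to [0, 1];
* density is the literal sum of all edge weights (each undirected edge
  counted once);
* modularity is the best weighted Newman Q found by greedy agglomeration
  followed by single-node refinement, never below the trivial
  one-community partition (Q = 0).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import AdjacencyMatrix

__all__ = [
    "GLOBAL_MEASURES",
    "LOCAL_MEASURES",
    "GraphFeatureBlock",
    "shortest_path_matrix",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficients",
    "transitivity",
    "betweenness_centrality",
    "degree_centrality",
    "modularity",
    "density",
    "graph_feature_block",
]

GLOBAL_MEASURES = (
    "characteristic_path_length",
    "global_efficiency",
    "transitivity",
    "modularity",
    "density",
)
LOCAL_MEASURES = (
    "clustering_coefficient",
    "local_efficiency",
    "betweenness_centrality",
    "degree_centrality",
)


def _weights(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    if isinstance(adj, AdjacencyMatrix):
        return adj.weights
    return np.asarray(adj, dtype=np.float64)


@dataclass
class GraphFeatureBlock:
    """5 global values + 4 per-node vectors with deterministic names."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")


# ---------------------------------------------------------------------------
# Paths and efficiencies
# ---------------------------------------------------------------------------

def shortest_path_matrix(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances over 1/weight edge lengths.

    Disconnected pairs get ``inf``; the diagonal is 0.
    """
    w = _weights(adj)
    n = w.shape[0]
    lengths = np.zeros_like(w)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    if n < 2:
        return np.zeros((n, n))
    # dense zeros are interpreted as missing edges by csgraph
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def characteristic_path_length(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean shortest-path distance over all ordered node pairs."""
    d = shortest_path_matrix(adj)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        bad = np.argwhere(np.isinf(d) & off)[0]
        raise ValueError(
            f"graph is disconnected (no path between nodes "
            f"{bad[0]} and {bad[1]})"
        )
    return float(d[off].mean())


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[np.isinf(d[off])] = 0.0
    return float(inv.mean())


def global_efficiency(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path distance; defined on disconnected graphs."""
    return _efficiency_from_distances(shortest_path_matrix(adj))


def local_efficiency(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph."""
    w = _weights(adj)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        out[i] = global_efficiency(w[np.ix_(nbrs, nbrs)])
    return out


# ---------------------------------------------------------------------------
# Triangles
# ---------------------------------------------------------------------------

def _triangle_terms(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node geometric-mean triangle intensity t_i and binary degree k_i."""
    wmax = w.max()
    k = np.count_nonzero(w > 0, axis=1).astype(np.float64)
    if wmax == 0:
        return np.zeros(w.shape[0]), k
    cube = np.cbrt(w / wmax)
    t = np.diag(cube @ cube @ cube) / 2.0
    return t, k


def clustering_coefficients(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Weighted clustering C_i = 2 t_i / (k_i (k_i - 1)); 0 when k_i < 2."""
    w = _weights(adj)
    t, k = _triangle_terms(w)
    out = np.zeros(w.shape[0])
    ok = k >= 2
    out[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return out


def transitivity(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Graph-level closed-to-total triplet ratio, weighted analogue."""
    w = _weights(adj)
    t, k = _triangle_terms(w)
    denom = float(np.sum(k * (k - 1.0)))
    if denom == 0:
        return 0.0
    return float(2.0 * t.sum() / denom)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def betweenness_centrality(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Fraction of all-pairs shortest paths through each node, in [0, 1].

    Brandes accumulation on 1/weight lengths with shortest-path
    multiplicities; normalized by (n-1)(n-2).
    """
    w = _weights(adj)
    n = w.shape[0]
    bc = np.zeros(n)
    if n < 3:
        return bc
    lengths = np.full_like(w, np.inf)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    neighbours = [np.flatnonzero(pos[i]) for i in range(n)]
    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        dist[s] = 0.0
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        done = np.zeros(n, dtype=bool)
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d_v, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for u in neighbours[v]:
                alt = d_v + lengths[v, u]
                tol = 1e-12 * (1.0 + abs(alt))
                if alt < dist[u] - tol:
                    dist[u] = alt
                    sigma[u] = sigma[v]
                    preds[u] = [v]
                    heapq.heappush(heap, (alt, u))
                elif abs(alt - dist[u]) <= tol and not done[u]:
                    sigma[u] += sigma[v]
                    preds[u].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc / ((n - 1.0) * (n - 2.0))


def degree_centrality(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    """Node strength: sum of incident edge weights."""
    return _weights(adj).sum(axis=1)


def density(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Sum of all edge weights, each undirected edge counted once."""
    return float(_weights(adj).sum() / 2.0)


# ---------------------------------------------------------------------------
# Modularity
# ---------------------------------------------------------------------------

def partition_modularity(
    adj: AdjacencyMatrix | np.ndarray, communities: np.ndarray
) -> float:
    """Weighted Newman Q of a given node-to-community assignment."""
    w = _weights(adj)
    m2 = w.sum()  # = 2m
    if m2 == 0:
        return 0.0
    s = w.sum(axis=1)
    same = communities[:, None] == communities[None, :]
    return float(np.sum((w - np.outer(s, s) / m2)[same]) / m2)


def _greedy_merge(w: np.ndarray) -> np.ndarray:
    """Agglomerate singleton communities while any merge increases Q."""
    n = w.shape[0]
    m2 = w.sum()
    s = w.sum(axis=1)
    comms: dict[int, list[int]] = {i: [i] for i in range(n)}
    # e[a][b] = total weight between communities a and b; a_s = strength sums
    inter = {a: dict() for a in comms}
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                inter[i][j] = w[i, j]
                inter[j][i] = w[i, j]
    strength = {a: s[a] for a in comms}
    while len(comms) > 1:
        best = (0.0, None, None)
        for a in comms:
            for b, wab in inter[a].items():
                if b <= a:
                    continue
                dq = 2.0 * (wab / m2 - strength[a] * strength[b] / (m2 * m2))
                if dq > best[0] + 1e-15:
                    best = (dq, a, b)
        if best[1] is None:
            break
        _, a, b = best
        comms[a].extend(comms.pop(b))
        strength[a] += strength.pop(b)
        for c, wcb in inter.pop(b).items():
            if c == a:
                continue
            inter[c].pop(b, None)
            inter[a][c] = inter[a].get(c, 0.0) + wcb
            inter[c][a] = inter[a][c]
        inter[a].pop(b, None)
        inter[a].pop(a, None)
    labels = np.empty(n, dtype=np.intp)
    for idx, members in enumerate(comms.values()):
        labels[members] = idx
    return labels


def _refine(w: np.ndarray, labels: np.ndarray, max_passes: int = 20) -> np.ndarray:
    """Move single nodes between communities while Q improves."""
    labels = labels.copy()
    n = w.shape[0]
    for _ in range(max_passes):
        improved = False
        base = partition_modularity(w, labels)
        for i in range(n):
            current = labels[i]
            candidates = set(labels[np.flatnonzero(w[i] > 0)])
            candidates.add(int(labels.max()) + 1)  # allow splitting off
            best_q, best_c = base, current
            for c in candidates:
                if c == current:
                    continue
                labels[i] = c
                q = partition_modularity(w, labels)
                if q > best_q + 1e-12:
                    best_q, best_c = q, c
            labels[i] = best_c
            if best_c != current:
                base = best_q
                improved = True
        if not improved:
            break
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def community_partition(
    adj: AdjacencyMatrix | np.ndarray, seed: int = 0
) -> np.ndarray:
    """Community labels from greedy agglomeration plus node refinement.

    The procedure is deterministic; ``seed`` is accepted for config
    compatibility and reserved for future stochastic restarts.
    """
    w = _weights(adj)
    if w.sum() == 0:
        return np.zeros(w.shape[0], dtype=np.intp)
    labels = _greedy_merge(w)
    return _refine(w, labels)


def modularity(adj: AdjacencyMatrix | np.ndarray, seed: int = 0) -> float:
    """Best weighted Newman Q found; never below the one-community Q = 0."""
    w = _weights(adj)
    if w.sum() == 0:
        return 0.0
    q = partition_modularity(w, community_partition(w, seed=seed))
    return max(q, 0.0)


# ---------------------------------------------------------------------------
# Feature block
# ---------------------------------------------------------------------------

def graph_feature_block(adj: AdjacencyMatrix, seed: int = 0) -> GraphFeatureBlock:
    """5 globals then 4 per-node vectors; length 5 + 4n."""
    labels = adj.node_labels
    global_values = [
        characteristic_path_length(adj),
        global_efficiency(adj),
        transitivity(adj),
        modularity(adj, seed=seed),
        density(adj),
    ]
    local_vectors = [
        clustering_coefficients(adj),
        local_efficiency(adj),
        betweenness_centrality(adj),
        degree_centrality(adj),
    ]
    names = list(GLOBAL_MEASURES)
    for measure, _vec in zip(LOCAL_MEASURES, local_vectors):
        names.extend(f"{measure}__{ch}" for ch in labels)
    values = np.concatenate([np.asarray(global_values), *local_vectors])
    return GraphFeatureBlock(values=values, names=names)
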