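"""Definition-level brute-force oracles, kept independent of the package
implementations they check: explicit loops, exhaustive enumeration, and
textbook recurrences only."""

from __future__ import annotations

from itertools import combinations

import numpy as np


# ---------------------------------------------------------------------------
# Distances / efficiency
# ---------------------------------------------------------------------------

def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on 1/weight lengths via the FW recurrence."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_oracle(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    n = d.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) >= 2:
            out[i] = global_efficiency_oracle(weights[np.ix_(nbrs, nbrs)])
    return out


# ---------------------------------------------------------------------------
# Triangles
# ---------------------------------------------------------------------------

def clustering_oracle(weights: np.ndarray) -> np.ndarray:
    """Triple-loop geometric-mean clustering on max-normalized weights."""
    n = weights.shape[0]
    wmax = weights.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    norm = weights / wmax
    for i in range(n):
        k = sum(1 for j in range(n) if weights[i, j] > 0)
        if k < 2:
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (norm[i, j] * norm[i, h] * norm[j, h]) ** (1.0 / 3.0)
        t /= 2.0
        out[i] = 2.0 * t / (k * (k - 1))
    return out


def transitivity_oracle(weights: np.ndarray) -> float:
    n = weights.shape[0]
    wmax = weights.max()
    if wmax == 0:
        return 0.0
    norm = weights / wmax
    numer = 0.0
    denom = 0.0
    for i in range(n):
        k = sum(1 for j in range(n) if weights[i, j] > 0)
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (norm[i, j] * norm[i, h] * norm[j, h]) ** (1.0 / 3.0)
        numer += t  # = 2 t_i
        denom += k * (k - 1)
    return numer / denom if denom else 0.0


def binary_clustering_oracle(adjacency01: np.ndarray) -> np.ndarray:
    """Classic unweighted clustering by triangle counting."""
    n = adjacency01.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adjacency01[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in combinations(nbrs, 2) if adjacency01[a, b] > 0
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def binary_transitivity_oracle(adjacency01: np.ndarray) -> float:
    """3 x triangles / connected triplets, counted exhaustively."""
    n = adjacency01.shape[0]
    triangles = 0
    triplets = 0
    for i, j, h in combinations(range(n), 3):
        edges = (
            int(adjacency01[i, j] > 0)
            + int(adjacency01[i, h] > 0)
            + int(adjacency01[j, h] > 0)
        )
        if edges == 3:
            triangles += 1
        # each centre with two incident edges is one open/closed triplet
        for centre, a, b in ((i, j, h), (j, i, h), (h, i, j)):
            if adjacency01[centre, a] > 0 and adjacency01[centre, b] > 0:
                triplets += 1
    return 3.0 * triangles / triplets if triplets else 0.0


# ---------------------------------------------------------------------------
# Betweenness by exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def betweenness_oracle(weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Enumerate all simple paths per pair; count shortest-path interiors."""
    n = weights.shape[0]
    bc = np.zeros(n)
    if n < 3:
        return bc

    def all_paths(s: int, t: int):
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                yield path, length
                continue
            for nxt in range(n):
                if weights[node, nxt] > 0 and nxt not in path:
                    stack.append((nxt, path + [nxt], length + 1.0 / weights[node, nxt]))

    for s, t in combinations(range(n), 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        dmin = min(length for _, length in paths)
        shortest = [p for p, length in paths if length <= dmin + tol]
        for path in shortest:
            for interior in path[1:-1]:
                bc[interior] += 1.0 / len(shortest)
    return bc / ((n - 1) * (n - 2) / 2.0)


# ---------------------------------------------------------------------------
# Modularity by exhaustive partition search
# ---------------------------------------------------------------------------

def _set_partitions(items: list[int]):
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in _set_partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def modularity_oracle(weights: np.ndarray) -> float:
    """Best Q over every partition of the node set (feasible for n <= 7)."""
    n = weights.shape[0]
    m2 = weights.sum()
    if m2 == 0:
        return 0.0
    s = weights.sum(axis=1)
    best = -np.inf
    for part in _set_partitions(list(range(n))):
        q = 0.0
        for block in part:
            for i in block:
                for j in block:
                    q += weights[i, j] - s[i] * s[j] / m2
        best = max(best, q / m2)
    return best


# ---------------------------------------------------------------------------
# Approximate entropy, O(N^2) per-template loops
# ---------------------------------------------------------------------------

def apen_oracle(x: np.ndarray, m: int, r: float) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size

    def phi(mm: int) -> float:
        count = n - mm + 1
        logs = 0.0
        for i in range(count):
            template = x[i : i + mm]
            matches = 0
            for j in range(count):
                if np.max(np.abs(template - x[j : j + mm])) <= r:
                    matches += 1
            logs += np.log(matches / count)
        return logs / count

    return phi(m) - phi(m + 1)


# ---------------------------------------------------------------------------
# Mutual information via an independent histogram routine
# ---------------------------------------------------------------------------

def mi_oracle(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(
        x, y, bins=bins, range=[[x.min(), x.max()], [y.min(), y.max()]]
    )
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in range(bins):
        for b in range(bins):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log2(joint[a, b] / (px[a] * py[b]))
    return max(mi, 0.0)
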