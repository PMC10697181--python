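"""Independent brute-force oracles used to validate the graph measures.

Everything here is written in the most literal way possible (triple loops,
Floyd-Warshall dynamic programming, shortest-path counting by exhaustive
simple-path enumeration or predecessor recursion, exhaustive weight-placement
enumeration) and shares no code with the implementations it checks.
"""

from itertools import permutations

import numpy as np


def onnela_clustering_bruteforce(w: np.ndarray) -> np.ndarray:
    """Triple-loop geometric-mean triangle intensity on max-normalized weights."""
    n = w.shape[0]
    mx = w.max()
    wn = w / mx if mx > 0 else w
    out = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                if w[i, j] > 0 and w[i, h] > 0 and w[j, h] > 0:
                    total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the classic O(n^3) dynamic program."""
    n = lengths.shape[0]
    d = lengths.copy().astype(float)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def char_path_length_bruteforce(lengths: np.ndarray) -> float:
    d = floyd_warshall(lengths)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def betweenness_bruteforce(lengths: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unnormalized betweenness via shortest-path counting (predecessor DP).

    Requires generic inputs: strictly positive edge lengths with no exact
    distance ties, so the predecessor relation is a DAG ordered by distance.
    """
    n = lengths.shape[0]
    d = floyd_warshall(lengths)
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1.0
        targets = sorted(
            (t for t in range(n) if t != s and np.isfinite(d[s, t])),
            key=lambda t: d[s, t],
        )
        for t in targets:
            total = 0.0
            for v in range(n):
                if v == t or not np.isfinite(lengths[v, t]):
                    continue
                if abs(d[s, v] + lengths[v, t] - d[s, t]) <= tol:
                    total += sigma[s, v]
            sigma[s, t] = total
    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) <= tol:
                    btw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return btw


def betweenness_path_enumeration(lengths: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Betweenness by exhaustively enumerating every simple path (tiny n only)."""
    n = lengths.shape[0]
    neighbors = [list(np.flatnonzero(np.isfinite(lengths[i]))) for i in range(n)]

    def all_paths(s, t):
        paths = []

        def extend(path, cost):
            u = path[-1]
            if u == t:
                paths.append((list(path), cost))
                return
            for v in neighbors[u]:
                if v not in path:
                    path.append(v)
                    extend(path, cost + lengths[u, v])
                    path.pop()

        extend([s], 0.0)
        return paths

    btw = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            best = min(c for _, c in paths)
            shortest = [p for p, c in paths if c <= best + tol]
            for p in shortest:
                for v in p[1:-1]:
                    btw[v] += 1.0 / len(shortest)
    return btw


def rich_club_bruteforce(w: np.ndarray, k: int, weighted: bool):
    """Single-k rich-club coefficient by direct recomputation."""
    binary = w != 0
    degree = binary.sum(axis=1)
    nodes = [i for i in range(len(w)) if degree[i] > k]
    if len(nodes) < 2:
        return float("nan")
    club_edges = [(i, j) for a, i in enumerate(nodes) for j in nodes[a + 1 :] if binary[i, j]]
    if not weighted:
        return 2.0 * len(club_edges) / (len(nodes) * (len(nodes) - 1))
    if not club_edges:
        return 0.0
    club_w = sum(w[i, j] for i, j in club_edges)
    all_w = sorted(
        (w[i, j] for i in range(len(w)) for j in range(i + 1, len(w)) if binary[i, j]),
        reverse=True,
    )
    return club_w / sum(all_w[: len(club_edges)])


def strength_energy(edges, weights, target, n) -> float:
    s = np.zeros(n)
    for (a, b), w in zip(edges, weights):
        s[a] += w
        s[b] += w
    return float(((s - target) ** 2).sum())


def optimal_placement_energy(edges, weights, target, n) -> float:
    """Global minimum of the strength-matching energy over all weight placements."""
    best = np.inf
    for perm in permutations(range(len(weights))):
        e = strength_energy(edges, [weights[p] for p in perm], target, n)
        if e < best:
            best = e
    return best


def spearman_rank_pearson(x, y) -> float:
    """Rank both vectors with average ranks, then plain Pearson."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
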