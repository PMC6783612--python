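"""Independent brute-force oracles for small graphs.

Everything here works by exhaustive enumeration of simple paths, so it
shares no code path with the package's Dijkstra/Brandes machinery.
Only usable for N <= ~9 nodes.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-9


def _edge_length(w: float, mode: str) -> float:
    return 1.0 if mode == "binary" else 1.0 / w


def _all_simple_paths(w: np.ndarray, s: int, t: int, mode: str):
    """Yield (length, path) for every simple path from s to t."""
    n = w.shape[0]
    stack = [(s, [s], 0.0)]
    while stack:
        v, path, length = stack.pop()
        if v == t:
            yield length, path
            continue
        for u in range(n):
            if w[v, u] > 0 and u not in path:
                stack.append((u, path + [u],
                              length + _edge_length(w[v, u], mode)))


def shortest_paths_brute(w: np.ndarray, mode: str = "weighted"):
    """Distance matrix plus, per unordered pair, the list of shortest paths."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    paths = {}
    for s in range(n):
        for t in range(s + 1, n):
            found = list(_all_simple_paths(w, s, t, mode))
            if not found:
                paths[(s, t)] = []
                continue
            best = min(length for length, _ in found)
            dist[s, t] = dist[t, s] = best
            paths[(s, t)] = [p for length, p in found
                             if length <= best + TOL * (1.0 + best)]
    return dist, paths


def global_efficiency_brute(w: np.ndarray, mode: str = "weighted") -> float:
    n = w.shape[0]
    dist, _ = shortest_paths_brute(w, mode)
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(dist[s, t]):
                total += 1.0 / dist[s, t]
    return total / (n * (n - 1))


def local_efficiency_brute(w: np.ndarray, mode: str = "weighted") -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.flatnonzero(w[v] > 0)
        if len(nb) < 2:
            continue
        out[v] = global_efficiency_brute(w[np.ix_(nb, nb)], mode)
    return out


def betweenness_brute(w: np.ndarray, mode: str = "weighted") -> np.ndarray:
    """Unnormalized betweenness over unordered pairs s != t != v."""
    n = w.shape[0]
    _, paths = shortest_paths_brute(w, mode)
    bc = np.zeros(n)
    for (s, t), plist in paths.items():
        sigma = len(plist)
        if sigma == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in plist if v in p[1:-1])
            bc[v] += through / sigma
    return bc
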