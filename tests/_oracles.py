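"""Independent brute-force oracles for small digraphs.

Betweenness and closeness are recomputed here from explicit enumeration of
all shortest paths, with no shared code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def _all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest s->t path, by breadth-limited DFS over edges."""
    n = adj.shape[0]
    # BFS distances from s
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u, v] and v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if adj[u, v] and dist.get(v) == dist[u] + 1 and dist[v] <= dist[t]:
                extend(path + [v])

    extend([s])
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Directed betweenness, normalised by (n-1)(n-2)."""
    n = adj.shape[0]
    score = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = _all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                on = sum(1 for p in paths if v in p[1:-1])
                score[v] += on / len(paths)
    return score / ((n - 1) * (n - 2))


def brute_closeness(adj: np.ndarray) -> np.ndarray:
    """Incoming-distance closeness with the Wasserman-Faust correction."""
    n = adj.shape[0]
    out = np.zeros(n)
    for u in range(n):
        # distances TO u along directed edges
        dists = []
        for s in range(n):
            if s == u:
                continue
            paths = _all_shortest_paths(adj, s, u)
            if paths:
                dists.append(len(paths[0]) - 1)
        r = len(dists)
        if r == 0 or sum(dists) == 0:
            out[u] = 0.0
        else:
            out[u] = (r / (n - 1)) * (r / sum(dists))
    return out
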