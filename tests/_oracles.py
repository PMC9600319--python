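"""Independent brute-force oracles used by the tests.

Deliberately naive and self-contained: hand-rolled BFS and pruned DFS
path enumeration (no networkx), so they provide an independent check of
the package's centrality computations.
"""

from __future__ import annotations

import itertools
from collections import deque


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def _shortest_paths(adj: dict, s, t, d: int) -> list[tuple]:
    """All s-t paths of length exactly d, by depth-limited DFS."""
    out = []
    stack = [(s, (s,))]
    while stack:
        u, path = stack.pop()
        if len(path) - 1 == d:
            if u == t:
                out.append(path)
            continue
        for w in adj[u]:
            if w not in path:
                stack.append((w, path + (w,)))
    return out


def brute_force_centrality(nodes, edges):
    """(betweenness, closeness, distances) by exhaustive path enumeration.

    Betweenness: for every unordered pair (s, t), every shortest path is
    enumerated and each interior node credited with its fraction.
    Closeness: reciprocal of the BFS distance sum (within the node's
    connected component; 0 for isolated nodes).
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    btw = {v: 0.0 for v in nodes}
    clo = {}
    dists = {}
    for s, t in itertools.combinations(sorted(nodes, key=str), 2):
        d = bfs_distances(adj, s)
        if t not in d:
            continue
        dists[(s, t)] = d[t]
        paths = _shortest_paths(adj, s, t, d[t])
        for v in nodes:
            if v in (s, t):
                continue
            hits = sum(1 for p in paths if v in p)
            btw[v] += hits / len(paths)
    for v in nodes:
        d = bfs_distances(adj, v)
        total = sum(d.values())
        clo[v] = 1.0 / total if total > 0 else 0.0
    return btw, clo, dists
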