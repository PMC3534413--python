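"""Independent brute-force oracles used to check the fast implementations.

Everything here enumerates explicitly (BFS path counting, pairwise wins,
combinatorial sums) and shares no code with the package's computation
paths.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(adj: dict, s, t, dist: dict) -> list[list]:
    """All shortest s->t paths by backtracking along decreasing distance."""
    if t not in dist:
        return []
    paths = []

    def back(v, tail):
        if v == s:
            paths.append([s] + tail)
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                back(u, [v] + tail)

    back(t, [])
    return paths


def brute_betweenness(adj: dict) -> dict:
    """Unnormalised betweenness: fractional credit over tied shortest paths,
    each unordered pair counted once."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist = bfs_distances(adj, s)
        paths = _all_shortest_paths(adj, s, t, dist)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def brute_closeness(adj: dict) -> dict:
    """1 / sum of distances to reachable nodes; 0 with no reachable peer."""
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(d for u, d in dist.items() if u != v)
        out[v] = 1.0 / total if total > 0 else 0.0
    return out


def mann_whitney_auc(scores: dict, positives: set) -> float:
    """Tie-corrected U/(P*N): wins + half-ties over positive-negative pairs."""
    pos = [scores[v] for v in scores if v in positives]
    neg = [scores[v] for v in scores if v not in positives]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = comb(N, n)
    hits = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return hits / total


def hypergeom_upper_tail_enumerated(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exhaustively enumerating all C(N, n) draws."""
    labelled = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(labelled.intersection(draw)) >= k:
            hits += 1
    return hits / total
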