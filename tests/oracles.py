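"""Independent brute-force oracles used only by the tests.

These deliberately avoid networkx and scipy: centralities come from explicit
enumeration of every simple path, and hypergeometric tails from enumeration
of every possible draw. They are exponential-time and only usable on tiny
inputs, which is the point — they cannot share a bug with the implementation.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Set, Tuple


def _all_paths(adj: Dict[str, Set[str]], s: str, t: str) -> List[Tuple[str, ...]]:
    """Every simple path from s to t, by exhaustive DFS."""
    paths: List[Tuple[str, ...]] = []
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + (nb,)))
    return paths


def brute_force_centralities(
    nodes: Sequence[str], edges: Iterable[Tuple[str, str]]
) -> Tuple[Dict[str, int], Dict[str, float], Dict[str, float]]:
    """(degree, normalized betweenness, component-local closeness) by enumeration.

    Betweenness: for every unordered pair (s, t), enumerate all simple paths,
    keep the shortest ones, and credit each interior node its fraction;
    normalize by (n-1)(n-2)/2 with n the full node count. Closeness:
    (|component|-1) / sum of shortest-path lengths; isolated nodes get 0.
    """
    nodes = list(nodes)
    adj: Dict[str, Set[str]] = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    degree = {v: len(adj[v]) for v in nodes}

    # all-pairs shortest distances and shortest-path counts through each node
    n = len(nodes)
    bc_raw = {v: 0.0 for v in nodes}
    dist: Dict[Tuple[str, str], int] = {}
    for s, t in combinations(nodes, 2):
        paths = _all_paths(adj, s, t)
        if not paths:
            continue
        dmin = min(len(p) for p in paths) - 1
        dist[(s, t)] = dist[(t, s)] = dmin
        shortest = [p for p in paths if len(p) - 1 == dmin]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc_raw[v] += through / len(shortest)
    denom = (n - 1) * (n - 2) / 2 if n > 2 else 1.0
    betweenness = {v: bc_raw[v] / denom for v in nodes}

    closeness = {}
    for v in nodes:
        dists = [dist[(v, u)] for u in nodes if u != v and (v, u) in dist]
        closeness[v] = (len(dists) / sum(dists)) if dists else 0.0
    return degree, betweenness, closeness


def hypergeom_tail_table_by_enumeration(N: int, n: int) -> Dict[Tuple[int, int], float]:
    """Upper-tail p for every (K, k) with one exhaustive pass over all C(N, n) draws.

    The universe is {0..N-1}; for the special set {0..K-1} a draw's overlap is
    the number of its elements below K, so one enumeration serves every K.
    Returns {(K, k): P(overlap >= k)} for all 1 <= K <= N, 0 <= k <= min(n, K).
    """
    counts = {K: [0] * (n + 1) for K in range(1, N + 1)}
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        for K in range(1, N + 1):
            overlap = sum(1 for x in draw if x < K)
            counts[K][overlap] += 1
    table: Dict[Tuple[int, int], float] = {}
    for K in range(1, N + 1):
        for k in range(0, min(n, K) + 1):
            table[(K, k)] = sum(counts[K][k:]) / total
    return table


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(|draw ∩ special| >= k) by enumerating all C(N, n) draws of size n.

    The universe is {0..N-1} with specials {0..K-1}; feasible only for small N.
    """
    special = set(range(K))
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total
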