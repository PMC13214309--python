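"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths (and, where possible, the
libraries) they validate: betweenness by exhaustive shortest-path
enumeration, the hypergeometric tail by pmf summation with exact integer
binomials, and BH by the textbook step-up definition evaluated per rank.
"""

from __future__ import annotations

import itertools
import math


def _bfs_dist(adj, src):
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_force_betweenness(edges, nodes):
    """Pair-normalized betweenness by enumerating every shortest path.

    Normalization is component-local: each connected component of size
    n_c contributes fractions of its (n_c-1)(n_c-2)/2 pairs; components
    smaller than 3 contribute zeros.
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {n: 0.0 for n in nodes}
    seen: set = set()
    for start in nodes:
        if start in seen:
            continue
        comp = sorted(_bfs_dist(adj, start))
        seen.update(comp)
        n_c = len(comp)
        if n_c < 3:
            continue
        norm = (n_c - 1) * (n_c - 2) / 2.0
        for s, t in itertools.combinations(comp, 2):
            dist_s = _bfs_dist(adj, s)
            dist_t = _bfs_dist(adj, t)
            d = dist_s[t]
            paths: list[tuple] = []

            def extend(u, path):
                if u == t:
                    paths.append(path)
                    return
                for v in adj[u]:
                    if dist_s.get(v) == dist_s[u] + 1 and dist_s[v] + dist_t.get(v, 1 << 30) == d:
                        extend(v, path + (v,))

            extend(s, (s,))
            counts: dict = {}
            for path in paths:
                for w in path[1:-1]:
                    counts[w] = counts.get(w, 0) + 1
            for w, c in counts.items():
                out[w] += c / len(paths) / norm
    return out


def hypergeom_tail_by_summation(k, K, n, N):
    """P(X >= k) as an exact rational pmf sum over the upper support."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_step_up(p_values):
    """Textbook BH: adj for rank r is min over ranks >= r of m*p_(j)/j."""
    indexed = sorted(range(len(p_values)), key=lambda i: p_values[i])
    m = len(p_values)
    out = [0.0] * m
    for pos, i in enumerate(indexed, start=1):
        candidates = [
            m * p_values[j] / rank
            for rank, j in enumerate(indexed, start=1)
            if rank >= pos
        ]
        out[i] = min(1.0, min(candidates))
    return out
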