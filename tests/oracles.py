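"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration and exact
rational arithmetic — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb


# ---------------------------------------------------------------------------
# graph centralities by exhaustive path enumeration (graphs with few nodes)
# ---------------------------------------------------------------------------


def enumerate_all_paths(adj: dict, s, t) -> list[tuple]:
    """All simple paths from s to t by DFS."""
    paths = []

    def walk(node, seen, path):
        if node == t:
            paths.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in seen:
                walk(nxt, seen | {nxt}, path + [nxt])

    walk(s, {s}, [s])
    return paths


def brute_force_centralities(nodes: list, edges: list[tuple]) -> dict:
    """degree, betweenness (component-normalized), closeness
    (component-local), and stress for every node, from explicit enumeration
    of all shortest paths."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    # connected components by exhaustive reachability
    comp_of = {}
    for v in nodes:
        if v in comp_of:
            continue
        members = {v}
        frontier = {v}
        while frontier:
            frontier = {w for u in frontier for w in adj[u]} - members
            members |= frontier
        for m in members:
            comp_of[m] = frozenset(members)

    shortest: dict[tuple, list[tuple]] = {}
    dist: dict[tuple, int] = {}
    for s, t in itertools.combinations(nodes, 2):
        if comp_of[s] != comp_of[t]:
            continue
        paths = enumerate_all_paths(adj, s, t)
        d = min(len(p) for p in paths) - 1
        shortest[(s, t)] = [p for p in paths if len(p) - 1 == d]
        dist[(s, t)] = dist[(t, s)] = d

    out = {}
    for v in nodes:
        degree = len(adj[v])
        stress = 0
        betweenness = Fraction(0)
        for (s, t), paths in shortest.items():
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            stress += through
            betweenness += Fraction(through, len(paths))
        n = len(comp_of[v])
        if n > 2:
            betweenness = betweenness / Fraction((n - 1) * (n - 2), 2)
        total_dist = sum(dist[(v, u)] for u in comp_of[v] if u != v)
        closeness = Fraction(n - 1, total_dist) if total_dist else Fraction(0)
        out[v] = {
            "degree": degree,
            "betweenness": float(betweenness),
            "closeness": float(closeness),
            "stress": stress,
        }
    return out


# ---------------------------------------------------------------------------
# exact hypergeometric upper tail
# ---------------------------------------------------------------------------


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational."""
    denom = comb(N, n)
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return total


# ---------------------------------------------------------------------------
# exact two-sided Fisher p by table enumeration
# ---------------------------------------------------------------------------


def fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Sum of hypergeometric probabilities of all tables with the same
    margins that are as or less probable than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = comb(N, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return total


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up by hand
# ---------------------------------------------------------------------------


def bh_stepup(p_values: list[float]) -> list[float]:
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
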