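"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately naive (O(n^2)/O(n^3) scans, exhaustive
enumeration, dense linear algebra) and shares no code path with the
package implementations it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Graph centralities


def dense_centralities(nodes, edges):
    """(degree, betweenness, closeness, hub) via all-pairs BFS and dense eigh."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v in edges:
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1.0
    degree = a.sum(axis=1)

    # BFS per source: distances and shortest-path counts
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        dist[s, s] = 0
        sigma[s, s] = 1
        frontier = [s]
        d = 0
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.nonzero(a[u])[0]:
                    if np.isinf(dist[s, v]):
                        dist[s, v] = d + 1
                        nxt.append(v)
                    if dist[s, v] == d + 1:
                        sigma[s, v] += sigma[s, u]
            frontier = sorted(set(nxt))
            d += 1

    betweenness = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or not np.isfinite(dist[s, t]):
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    betweenness[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    betweenness /= 2.0  # unordered pairs on an undirected graph

    closeness = np.empty(n)
    for v in range(n):
        finite = dist[v][np.isfinite(dist[v])]
        total = finite.sum()
        closeness[v] = 1.0 / total if total > 0 else np.nan

    if a.any():
        eigvals, eigvecs = np.linalg.eigh(a)
        hub = np.abs(eigvecs[:, np.argmax(eigvals)])
        hub = hub / hub.max()
    else:
        hub = np.zeros(n)
    return degree, betweenness, closeness, hub


# ---------------------------------------------------------------------------
# Operon clustering / adaptation calling


def interval_gap(a, b):
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def bruteforce_operons(genes, max_gap=5000):
    """Single-linkage components of the pairwise interval-gap graph, per strand.

    Returns a set of frozensets of gene_ids (memberships only).
    """
    out = set()
    for strand in ("+", "-"):
        sub = [g for g in genes if g.strand == strand]
        parent = list(range(len(sub)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                if interval_gap(sub[i], sub[j]) <= max_gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i, g in enumerate(sub):
            groups.setdefault(find(i), []).append(g.gene_id)
        out.update(frozenset(v) for v in groups.values())
    return out


def bruteforce_putative(members, flags, window_genes=10, max_gap=5000):
    """Exhaustive neighbor-window enumeration of the adaptation-operon rule."""
    for g in members:
        if not flags[g.gene_id].hypothetical:
            continue
        ranked = sorted(
            (h for h in members if h.gene_id != g.gene_id),
            key=lambda h: (interval_gap(g, h), h.start, h.gene_id),
        )
        window = [h for h in ranked[:window_genes] if interval_gap(g, h) <= max_gap]
        if any(flags[h.gene_id].adaptation for h in window):
            return True
    return False


# ---------------------------------------------------------------------------
# Statistics


def holm_stepdown(pvals):
    """Direct Holm step-down formula."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for k, i in enumerate(order):
        running = max(running, (m - k) * p[i])
        adj[i] = min(1.0, running)
    return adj


def exact_rank_sum_p(x, y):
    """Two-sided exact Mann-Whitney p by itertools enumeration (Fractions)."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(a, b):
        u = Fraction(0)
        for ai in a:
            for bj in b:
                if ai > bj:
                    u += 1
                elif ai == bj:
                    u += Fraction(1, 2)
        return u

    u_obs = u_stat(x, y)
    total = comb(n + m, n)
    le = ge = 0
    for idx in combinations(range(n + m), n):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n + m) if i not in set(idx)]
        u = u_stat(chosen, rest)
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    p = 2 * min(Fraction(le, total), Fraction(ge, total))
    return float(min(1, p))


def exact_fisher_p(table):
    """Two-sided Fisher exact p: sum of table probabilities <= observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return Fraction(comb(r1, k) * comb(r2, c1 - k), comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(min(1, total))
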