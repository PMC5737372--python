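"""Independent reference implementations used as test oracles.

Everything here follows the definitions naively (full sorts, explicit
loops, exact summation) and is deliberately separate from the package's
optimized code paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np

SYMBOL_CLASSES = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "U": {"U"},
    "R": {"A", "G"}, "Y": {"C", "U"}, "N": {"A", "C", "G", "U"},
}


def floyd_warshall(nodes, edges):
    """O(n^3) Floyd-Warshall on unit weights; returns dict-of-dict."""
    inf = math.inf
    d = {u: {v: (0 if u == v else inf) for v in nodes} for u in nodes}
    for u, v in edges:
        d[u][v] = d[v][u] = 1
    for w in nodes:
        for u in nodes:
            duw = d[u][w]
            if duw is inf:
                continue
            row_w = d[w]
            row_u = d[u]
            for v in nodes:
                alt = duw + row_w[v]
                if alt < row_u[v]:
                    row_u[v] = alt
    return d


def naive_tppd(distance_of, members, top_fraction=0.1):
    """Definition-following TPPD: full sorts, explicit tie-breaks.

    ``distance_of(u, v)`` returns the hop distance.  Returns (l, D dict,
    core tuple, statistic).
    """
    members = sorted(set(members))
    n = len(members)
    l = math.floor(top_fraction * n + 0.5)
    l = max(1, min(l, n - 1))
    d_values = {}
    for u in members:
        dists = sorted(distance_of(u, v) for v in members if v != u)
        d_values[u] = sum(dists[:l])
    core = sorted(members, key=lambda u: (d_values[u], u))[:l]
    return l, d_values, tuple(core), sum(d_values[u] for u in core)


def naive_match(pattern, seq):
    """Character-class scan for degenerate motif matching."""
    hits = []
    L = len(pattern)
    for i in range(len(seq) - L + 1):
        if all(seq[i + j] in SYMBOL_CLASSES[pattern[j]] for j in range(L)):
            hits.append(i)
    return hits


def naive_average_linkage(dmat):
    """Textbook O(n^3) agglomeration; returns sorted merge heights.

    Inter-cluster distance is the mean over all cross pairs of the
    *original* pairwise distances (UPGMA).
    """
    n = dmat.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = np.mean([dmat[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)] + [merged]
    return sorted(heights)


def exact_binom_upper(n, x, p=Fraction(1, 2)):
    """Exact Pr[X >= x] for X ~ Binomial(n, p), via summation."""
    total = Fraction(0)
    for i in range(x, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return float(total)


def hypergeom_upper_bruteforce(pop, successes, draws, x):
    """Exact Pr[X >= x] for the hypergeometric, by direct summation."""
    total = Fraction(0)
    denom = math.comb(pop, draws)
    for i in range(x, min(successes, draws) + 1):
        total += Fraction(math.comb(successes, i) * math.comb(pop - successes, draws - i), denom)
    return float(total)


def sequential_inclusion_probs(weights, k):
    """Exact per-element inclusion probabilities of sequential weighted
    sampling without replacement (enumerate all ordered draws)."""
    n = len(weights)
    incl = [Fraction(0)] * n
    for order in itertools.permutations(range(n), k):
        prob = Fraction(1)
        remaining = Fraction(sum(weights))
        for i in order:
            prob *= Fraction(weights[i]) / remaining
            remaining -= weights[i]
        for i in order:
            incl[i] += prob
    return [float(p) for p in incl]


def random_connected_graph(rng, n, p=0.15):
    """Seeded Erdos-Renyi graph, made connected by chaining components."""
    g = nx.Graph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j])
    comps = sorted(nx.connected_components(g), key=min)
    for a, b in zip(comps, comps[1:]):
        g.add_edge(min(a), min(b))
    return g
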