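"""Independent brute-force oracles used to check the implementation.

Everything here is written to be obviously correct on tiny inputs rather
than efficient, and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def cpm_bruteforce(nodes, edges, k):
    """k-clique percolation by exhaustive enumeration.

    Enumerates every k-subset of nodes, keeps those that are cliques, links
    two cliques when they share k-1 nodes, and returns the node sets of the
    connected components of that clique graph.
    """
    edgeset = {frozenset(e) for e in edges}

    def is_clique(subset):
        return all(frozenset(p) in edgeset for p in itertools.combinations(subset, 2))

    cliques = [frozenset(c) for c in itertools.combinations(sorted(nodes), k) if is_clique(c)]
    # union-find over cliques
    parent = list(range(len(cliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            parent[find(i)] = find(j)
    groups = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    return sorted((tuple(sorted(g)) for g in groups.values()), key=lambda c: (-len(c), c))


def hypergeom_upper_tail(N, K, n, x):
    """P(X >= x) for X ~ Hypergeometric(N, K, n), by direct summation."""
    denom = math.comb(N, n)
    total = 0
    for i in range(x, min(K, n) + 1):
        if n - i > N - K:
            continue
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def pooled_t(x, y):
    """Textbook pooled two-sample t statistic and two-sided P."""
    from scipy.stats import t as tdist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


def exact_mean_set_pvalue(t_values, member_values):
    """Exact permutation P: fraction of same-size subsets with larger mean."""
    m = len(member_values)
    observed = sum(member_values) / m
    count = 0
    total = 0
    for subset in itertools.combinations(t_values, m):
        total += 1
        if sum(subset) / m > observed:
            count += 1
    return count / total


def random_graph(rng, n_max=12, p=None):
    """Random simple graph as (nodes, edges) with string labels."""
    n = int(rng.integers(4, n_max + 1))
    if p is None:
        p = float(rng.uniform(0.2, 0.7))
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return nodes, edges
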