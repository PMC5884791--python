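"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorised code paths: scalar loops
over the published component formulas for the two-population F_ST estimator,
a hand per-site diversity formula, and exhaustive least-squares quartet
fitting for neighbor joining.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def wc_theta_scalar(genotypes_a: list[int], genotypes_b: list[int]) -> float:
    """Two-population Weir-Cockerham theta-hat from 0/1/2 genotype lists.

    Direct transcription of the 1984 variance components for r = 2
    populations: a (among populations), b (between individuals within) and
    c (within individuals); theta = a / (a + b + c).  Returns NaN when the
    denominator vanishes or a population has fewer than two genotypes.
    """
    r = 2
    pops = [genotypes_a, genotypes_b]
    n = [len(g) for g in pops]
    if min(n) < 2:
        return float("nan")
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if abs(denom) < 1e-300:
        return float("nan")
    return a / denom


def per_site_pi(genotypes: list[int]) -> float:
    """Per-site diversity c(n-c) / (n(n-1)/2) from 0/1/2 genotypes."""
    called = [g for g in genotypes if g >= 0]
    n = 2 * len(called)
    if n < 2:
        return 0.0
    c = sum(called)
    return c * (n - c) / (n * (n - 1) / 2)


def best_quartet_lstsq(d: np.ndarray):
    """Exhaustive quartet fit: best topology and branch lengths by least squares.

    For each of the three unrooted quartet topologies, solve for the five
    branch lengths minimising the squared error against the six pairwise
    distances; return (frozenset cherry, lengths dict, sse) of the best fit.
    """
    taxa = list(range(4))
    results = []
    for cherry in [(0, 1), (0, 2), (0, 3)]:
        i, j = cherry
        k, l = [t for t in taxa if t not in cherry]
        # unknowns: e_i, e_j, e_k, e_l, m (internal); rows = pairs
        rows, rhs = [], []
        for (x, y) in itertools.combinations(taxa, 2):
            coef = [0.0] * 5
            coef[x] = 1.0
            coef[y] = 1.0
            same_side = {x, y} == {i, j} or {x, y} == {k, l}
            if not same_side:
                coef[4] = 1.0
            rows.append(coef)
            rhs.append(d[x, y])
        sol, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
        pred = np.asarray(rows) @ sol
        sse = float(np.sum((pred - np.asarray(rhs)) ** 2))
        results.append((sse, frozenset(cherry), sol))
    sse, cherry, sol = min(results, key=lambda t: t[0])
    lengths = {t: float(sol[t]) for t in taxa}
    lengths["internal"] = float(sol[4])
    return cherry, lengths, sse


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """A random binary tree topology with positive branch lengths and its
    exact additive distance matrix (computed by path summation over an
    explicit graph, independent of the package's tree code)."""
    # build by sequential attachment: start with two taxa joined by an edge
    edges: dict[tuple[int, int], float] = {}
    next_node = n_taxa  # internal node ids from n_taxa upward

    def add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    add_edge(0, 1, float(rng.uniform(0.1, 1.0)))
    for taxon in range(2, n_taxa):
        # pick an existing edge, split it with a new internal node
        u, v = list(edges)[rng.integers(0, len(edges))]
        w = edges[(u, v)]
        split = float(rng.uniform(0.2, 0.8)) * w
        del edges[(u, v)], edges[(v, u)]
        mid = next_node
        next_node += 1
        add_edge(u, mid, split)
        add_edge(mid, v, w - split)
        add_edge(mid, taxon, float(rng.uniform(0.1, 1.0)))

    # all-pairs path lengths between leaves by BFS over the tree graph
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
    D = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for t in range(n_taxa):
            D[s, t] = dist[t]
    return D
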