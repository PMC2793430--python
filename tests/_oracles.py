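"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — exhaustive enumeration over Prufer
sequences, direct gamma-ratio evaluation, literal formula transcriptions —
and shares no code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy.special import gammaln


def prufer_decode(seq, L):
    """Standard Prufer decoding, written independently of the package."""
    seq = list(seq)
    degree = [1] * L
    for s in seq:
        degree[s] += 1
    edges = []
    for s in seq:
        for leaf in range(L):
            if degree[leaf] == 1:
                break
        edges.append((min(leaf, s), max(leaf, s)))
        degree[leaf] -= 1
        degree[s] -= 1
    u, v = [i for i in range(L) if degree[i] == 1]
    edges.append((u, v))
    return edges


def all_labeled_trees(L):
    """Every labelled tree on L nodes, as edge lists (L^(L-2) of them)."""
    if L == 2:
        return [[(0, 1)]]
    return [prufer_decode(s, L)
            for s in itertools.product(range(L), repeat=L - 2)]


def brute_tree_sum(w):
    """Sum over all spanning trees of the product of edge weights."""
    L = w.shape[0]
    return sum(math.prod(w[i, j] for i, j in t) for t in all_labeled_trees(L))


def brute_edge_posteriors(w):
    """P(edge in tree) = sum over trees containing it / sum over all trees."""
    L = w.shape[0]
    total = 0.0
    per_edge = np.zeros((L, L))
    for t in all_labeled_trees(L):
        p = math.prod(w[i, j] for i, j in t)
        total += p
        for i, j in t:
            per_edge[i, j] += p
            per_edge[j, i] += p
    return per_edge / total


def dirichlet_multinomial_log(counts, lam):
    """Direct gamma-ratio evaluation of the marginal likelihood."""
    counts = np.asarray(counts, dtype=float).ravel()
    k = counts.size
    n = counts.sum()
    out = gammaln(k * lam) - gammaln(n + k * lam)
    for c in counts:
        out += gammaln(c + lam) - gammaln(lam)
    return float(out)


def apc_on_shifted(values):
    """Product correction applied to min-shifted entries, written with loops."""
    v = np.array(values, dtype=float)
    L = v.shape[0]
    off = [v[i, j] for i in range(L) for j in range(L) if i != j]
    shifted = v - min(off)
    row_mean = np.zeros(L)
    for i in range(L):
        row_mean[i] = np.mean([shifted[i, j] for j in range(L) if j != i])
    overall = np.mean([shifted[i, j] for i in range(L) for j in range(i + 1, L)])
    out = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(L):
            if i != j:
                out[i, j] = (shifted[i, j] - row_mean[i] * row_mean[j] / overall
                             if overall != 0 else 0.0)
    return out


def chain_score_direct(z_edges, z_ab):
    return sum((z_ab - z) if z_ab > z else 0.0 for z in z_edges)


def brute_best_chain(n_nodes, edges, a, b, z_ab):
    """Exhaustive simple-path minimisation of the chain score.

    Returns (s_tot, n_steps, path) with the same tie-break order as the
    package (score, then fewest edges, then lexicographic path), or None.
    """
    G = nx.Graph()
    G.add_nodes_from(range(n_nodes))
    for i, j, z in edges:
        if {i, j} != {a, b}:
            G.add_edge(i, j, z=z)
    best = None
    if a not in G or b not in G:
        return None
    for path in nx.all_simple_paths(G, a, b):
        zs = [G[path[k]][path[k + 1]]["z"] for k in range(len(path) - 1)]
        key = (chain_score_direct(zs, z_ab), len(path) - 1, tuple(path))
        if best is None or key < best:
            best = key
    return best
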