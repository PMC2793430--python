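"""Chains of co-evolving contacts explaining distal statistical dependencies.

A strongly co-evolving but structurally distal pair (a, b) can often be
explained by a chain of contacts a - x1 - ... - b in which every contact
itself co-evolves at least as strongly as the pair.  The total score of a
chain is the summed shortfall of its contacts' Z-values below Z_ab:

    S_tot = sum_e (Z_ab - Z_e) * Theta(Z_ab - Z_e)

(Theta the Heaviside step), so S_tot = 0 means every contact on the chain
co-evolves more strongly than the pair it explains.  The final score of a
pair is s = S_tot / n_steps, the average shortfall per contact.  Minimal-
score chains are found by Dijkstra search with the non-negative edge costs
max(0, Z_ab - Z_e); significance is assessed by permuting the Z-values of
all contacts and re-scoring.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from coevotree.pair_stats import ScoreMatrix
from coevotree.structure_contacts import ContactMap

__all__ = [
    "ContactGraph", "ChainResult", "chain_score", "best_chain",
    "explain_distal_pairs", "permutation_null", "chain_statistics",
    "cumulative_s",
]


class ContactGraph:
    """Contact edges with attached Z-values and spatial distances."""

    def __init__(self, n_nodes: int):
        self.n_nodes = n_nodes
        self.adj: dict[int, dict[int, float]] = {i: {} for i in range(n_nodes)}
        self.dist: dict[tuple[int, int], float] = {}

    @classmethod
    def from_contact_map(cls, cm: ContactMap, z: ScoreMatrix) -> "ContactGraph":
        if z.n_cols != cm.n_cols:
            raise ValueError("Z matrix and contact map disagree on columns")
        g = cls(cm.n_cols)
        for i, j in cm.contact_pairs():
            zv = z.values[i, j]
            if np.isnan(zv):
                raise ValueError(f"contact ({i}, {j}) has undefined Z")
            g.add_edge(i, j, float(zv), float(cm.dist[i, j]))
        return g

    def add_edge(self, i: int, j: int, z: float, dist: float = np.nan) -> None:
        self.adj[i][j] = z
        self.adj[j][i] = z
        self.dist[(min(i, j), max(i, j))] = dist

    def edges(self) -> list[tuple[int, int, float]]:
        return [(i, j, z) for i, nbrs in self.adj.items()
                for j, z in nbrs.items() if i < j]

    def set_edge_z(self, i: int, j: int, z: float) -> None:
        self.adj[i][j] = z
        self.adj[j][i] = z


@dataclass
class ChainResult:
    """Best explaining chain for one distal pair."""

    pair: tuple[int, int]
    z_ab: float
    path: list[int]          # node sequence from a to b
    s_tot: float
    n_steps: int
    s: float                 # S_tot / n_steps
    spatial_distance: float  # Angstrom between a and b


def chain_score(z_edges, z_ab: float) -> float:
    """Total shortfall of a chain's contact Z-values below Z_ab."""
    z_edges = list(z_edges)
    if not z_edges:
        raise ValueError("chain must contain at least one edge")
    return float(sum(max(0.0, z_ab - z) for z in z_edges))


def best_chain(a: int, b: int, g: ContactGraph, z_ab: float,
               spatial_distance: float = np.nan) -> ChainResult | None:
    """Minimal-S_tot contact chain from a to b, or ``None`` if unreachable.

    The direct edge (a, b), if present in the graph, is excluded.  Among
    chains of equal S_tot the one with fewest contacts wins; remaining ties
    break on the lexicographically smallest node sequence.  Implemented as
    Dijkstra over the priority (cost, n_steps, path).
    """
    if a == b:
        raise ValueError("endpoints must differ")
    # heap entries: (cost, n_steps, path)
    heap: list[tuple[float, int, tuple[int, ...]]] = [(0.0, 0, (a,))]
    done: set[int] = set()
    while heap:
        cost, steps, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == b:
            z_list = [g.adj[path[k]][path[k + 1]] for k in range(len(path) - 1)]
            s_tot = chain_score(z_list, z_ab)
            return ChainResult(pair=(a, b), z_ab=z_ab, path=list(path),
                               s_tot=s_tot, n_steps=steps,
                               s=s_tot / steps,
                               spatial_distance=spatial_distance)
        for nbr, z_e in sorted(g.adj[node].items()):
            if nbr in done:
                continue
            if node == a and nbr == b:
                continue  # the pair itself is not a contact edge
            heapq.heappush(
                heap, (cost + max(0.0, z_ab - z_e), steps + 1, path + (nbr,)))
    return None


def explain_distal_pairs(z: ScoreMatrix, cm: ContactMap,
                         z_threshold: float = 4.0,
                         graph: ContactGraph | None = None) -> list[ChainResult]:
    """Best chains for every non-contacting pair with Z above the threshold.

    Pairs whose contact status is undefined (missing structure coverage) are
    skipped.  Unreachable pairs (different contact components) are omitted
    from the result list.
    """
    if graph is None:
        graph = ContactGraph.from_contact_map(cm, z)
    L = cm.n_cols
    results: list[ChainResult] = []
    for i in range(L):
        for j in range(i + 1, L):
            c = cm.contact[i, j]
            zv = z.values[i, j]
            if np.isnan(c) or c == 1.0 or np.isnan(zv) or zv <= z_threshold:
                continue
            res = best_chain(i, j, graph, float(zv),
                             spatial_distance=float(cm.dist[i, j]))
            if res is not None:
                results.append(res)
    return results


def cumulative_s(results: list[ChainResult], s_grid: np.ndarray) -> np.ndarray:
    """Fraction of pairs explained by a chain with score <= s, per grid point."""
    if not results:
        return np.zeros_like(np.asarray(s_grid, dtype=float))
    s_vals = np.array([r.s for r in results])
    return np.array([(s_vals <= s).mean() for s in np.asarray(s_grid)])


def permutation_null(results: list[ChainResult], cm: ContactMap,
                     z: ScoreMatrix, n_perm: int = 100,
                     seed: int = 0) -> np.ndarray:
    """Null distribution of s under permutation of the contacts' Z-values.

    For each permutation, the multiset of Z-values over the contact edges is
    shuffled (pair Z_ab values stay fixed), best chains are recomputed for
    the same distal pairs, and the resulting s values are pooled.
    Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    graph = ContactGraph.from_contact_map(cm, z)
    edge_list = graph.edges()
    z_values = np.array([e[2] for e in edge_list])
    null_s: list[float] = []
    for _ in range(n_perm):
        perm = rng.permutation(len(edge_list))
        for (i, j, _), zp in zip(edge_list, z_values[perm]):
            graph.set_edge_z(i, j, float(zp))
        for r in results:
            a, b = r.pair
            res = best_chain(a, b, graph, r.z_ab)
            if res is not None:
                null_s.append(res.s)
    return np.array(null_s)


def enrichment_curve(results: list[ChainResult], null_s: np.ndarray,
                     s_grid: np.ndarray) -> np.ndarray:
    """Real-over-null ratio of the fractions explained at score <= s."""
    real = cumulative_s(results, s_grid)
    if null_s.size == 0:
        return np.full_like(real, np.inf)
    null = np.array([(null_s <= s).mean() for s in np.asarray(s_grid)])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(null > 0, real / null, np.inf)


def chain_statistics(results: list[ChainResult],
                     contact_threshold: float = 8.0,
                     n_dist_bins: int = 10) -> dict:
    """Summary statistics of explaining chains.

    Returns a dict with

    ``distances``, ``reverse_cumulative``
        Sorted spatial distances of the explained pairs and the fraction of
        pairs at least that distant (a reverse-cumulative distribution).
    ``exp_scale``
        Exponential MLE length scale: the mean excess distance over the
        contact threshold (distal pairs are >= the threshold by definition).
    ``steps_by_distance``
        Per-distance-bin mean and SD of the number of chain steps.
    ``angstrom_per_step``
        Inverse slope of the least-squares fit of steps on distance; NaN
        when degenerate (single bin or zero slope).
    """
    if not results:
        raise ValueError("no chain results to summarise")
    dists = np.array([r.spatial_distance for r in results], dtype=float)
    steps = np.array([r.n_steps for r in results], dtype=float)
    order = np.argsort(dists)
    sorted_d = dists[order]
    rev_cum = 1.0 - np.arange(len(sorted_d)) / len(sorted_d)
    scale = float(np.mean(dists - contact_threshold)) if dists.size else np.nan

    lo, hi = float(dists.min()), float(dists.max())
    if hi == lo:
        edges = np.array([lo, lo + 1.0])
    else:
        edges = np.linspace(lo, hi + 1e-9, n_dist_bins + 1)
    idx = np.clip(np.digitize(dists, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            rows.append(((edges[b] + edges[b + 1]) / 2,
                         float(steps[sel].mean()),
                         float(steps[sel].std()),
                         int(sel.sum())))
    if len(set(steps)) > 1 and hi > lo:
        slope = np.polyfit(dists, steps, 1)[0]  # steps per Angstrom
        aps = float(1.0 / slope) if slope > 0 else np.nan
    else:
        aps = np.nan
    return {
        "distances": sorted_d,
        "reverse_cumulative": rev_cum,
        "exp_scale": scale,
        "steps_by_distance": rows,
        "angstrom_per_step": aps,
    }


def write_chains_tsv(results: list[ChainResult], path) -> None:
    """Serialize chains as ``a b Z_ab S_tot n_steps s path``."""
    with open(path, "w") as fh:
        fh.write("# a\tb\tz_ab\ts_tot\tn_steps\ts\tpath\n")
        for r in results:
            path_str = ",".join(map(str, r.path))
            fh.write(f"{r.pair[0]}\t{r.pair[1]}\t{r.z_ab:.6g}\t{r.s_tot:.6g}\t"
                     f"{r.n_steps}\t{r.s:.6g}\t{path_str}\n")
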