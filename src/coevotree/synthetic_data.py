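"""Synthetic alignments from planted dependence trees, and toy contact scenarios.

Sequences are drawn i.i.d. from the tree factorisation

    P(x_1 .. x_L) = P(x_root) * prod_{i != root} P(x_i | x_parent(i)),

with per-edge 20 x 20 conditional tables.  A scalar *coupling* in [0, 1]
interpolates between independence (0: every row of the conditional equals
the child's base distribution) and a deterministic permutation copy of the
parent (1).  The permutation is drawn per edge so that strongly coupled
columns are co-varying rather than trivially conserved.

Scenario generation plants a small contact graph with per-edge couplings,
generates data along a spanning forest of it, and returns the alignment
together with a toy contact map (from scenario coordinates) and the ground
truth — which pairs are directly coupled and which are indirect.  The
classic illustration is a five-residue system where A-B and B-C are strong
contacts and D-E a weaker one: the chain induces a strong *indirect*
dependency between the distal pair (A, C), so MI ranks (A, C) above (D, E)
while the tree posterior correctly demotes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from coevotree.msa_io import Alignment
from coevotree.structure_contacts import ContactMap, DistanceMap, build_contact_map

__all__ = [
    "TreeSpec", "ScenarioSpec", "sample_dependence_tree",
    "sample_conditional_tables", "generate_alignment",
    "generate_contact_scenario", "fig_scenario", "prufer_to_edges",
]


@dataclass
class TreeSpec:
    """A planted dependence forest with per-edge conditional tables.

    ``parent[i]`` is the parent column of i, or -1 for a root (several roots
    make a forest; independent components are generated independently).
    ``root_dist[r]`` is the 20-letter distribution of root r, and
    ``cond_tables[i]`` the row-stochastic P(x_i | x_parent(i)) for non-roots.
    """

    L: int
    parent: np.ndarray
    root_dist: dict[int, np.ndarray]
    cond_tables: dict[int, np.ndarray]
    coupling: float = field(default=np.nan)  # record-keeping only

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        if self.parent.shape != (self.L,):
            raise ValueError("parent array must have length L")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size == 0:
            raise ValueError("at least one root required")
        # check acyclicity by walking up from every node
        for i in range(self.L):
            seen = set()
            j = i
            while self.parent[j] >= 0:
                if j in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(j)
                j = self.parent[j]
        for r in roots:
            d = np.asarray(self.root_dist[int(r)], dtype=float)
            if d.shape != (20,) or not np.isclose(d.sum(), 1.0):
                raise ValueError(f"root {r} distribution malformed")
        for i in range(self.L):
            if self.parent[i] >= 0:
                t = np.asarray(self.cond_tables[i], dtype=float)
                if t.shape != (20, 20) or not np.allclose(t.sum(axis=1), 1.0):
                    raise ValueError(f"conditional table for column {i} malformed")

    def edges(self) -> list[tuple[int, int]]:
        return [(min(i, p), max(i, p))
                for i, p in enumerate(self.parent) if p >= 0]


def prufer_to_edges(seq: np.ndarray, L: int) -> list[tuple[int, int]]:
    """Decode a Prufer sequence of length L-2 into the edges of a labelled tree."""
    seq = list(seq)
    if L < 2:
        raise ValueError("L must be >= 2")
    if len(seq) != L - 2:
        raise ValueError("Prufer sequence must have length L-2")
    degree = np.ones(L, dtype=int)
    for s in seq:
        degree[s] += 1
    edges = []
    for s in seq:
        leaf = int(np.flatnonzero(degree == 1).min())
        edges.append((min(leaf, s), max(leaf, s)))
        degree[leaf] -= 1
        degree[s] -= 1
    u, v = np.flatnonzero(degree == 1)
    edges.append((int(u), int(v)))
    return edges


def _orient_edges(edges: list[tuple[int, int]], L: int,
                  roots: list[int] | None = None) -> np.ndarray:
    """Turn an undirected forest into parent links, rooting each component."""
    adj: dict[int, list[int]] = {i: [] for i in range(L)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    parent = np.full(L, -1, dtype=int)
    visited = np.zeros(L, dtype=bool)
    order = (roots or []) + [i for i in range(L) if not (roots and i in roots)]
    for r in order:
        if visited[r]:
            continue
        stack = [r]
        visited[r] = True
        while stack:
            node = stack.pop()
            for nbr in adj[node]:
                if not visited[nbr]:
                    visited[nbr] = True
                    parent[nbr] = node
                    stack.append(nbr)
    return parent


def sample_dependence_tree(L: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform random labelled tree on L nodes, as parent links rooted at 0.

    Uses the Prufer bijection: a uniform sequence in {0..L-1}^(L-2) maps to a
    uniform labelled tree.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if L == 2:
        edges = [(0, 1)]
    else:
        edges = prufer_to_edges(rng.integers(0, L, size=L - 2), L)
    return _orient_edges(edges, L, roots=[0])


def sample_conditional_tables(coupling: float,
                              seed: int | np.random.Generator = 0,
                              base: np.ndarray | None = None) -> np.ndarray:
    """One 20 x 20 row-stochastic conditional table at the given coupling.

    Row a is ``coupling * onehot(perm[a]) + (1 - coupling) * base`` with a
    seeded random alphabet permutation: coupling 0 detaches the child from
    the parent, coupling 1 makes it a deterministic (permuted) copy.
    """
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if base is None:
        base = rng.dirichlet(np.ones(20))
    base = np.asarray(base, dtype=float)
    perm = rng.permutation(20)
    table = np.tile((1.0 - coupling) * base, (20, 1))
    table[np.arange(20), perm] += coupling
    return table


def build_tree_spec(L: int, coupling: float = 0.9,
                    seed: int | np.random.Generator = 0,
                    parent: np.ndarray | None = None) -> TreeSpec:
    """A complete planted-tree specification: topology, roots, conditionals."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if parent is None:
        parent = sample_dependence_tree(L, rng)
    parent = np.asarray(parent, dtype=int)
    root_dist = {int(r): rng.dirichlet(np.ones(20))
                 for r in np.flatnonzero(parent < 0)}
    cond = {i: sample_conditional_tables(coupling, rng)
            for i in range(L) if parent[i] >= 0}
    return TreeSpec(L=L, parent=parent, root_dist=root_dist,
                    cond_tables=cond, coupling=coupling)


def _topological_order(parent: np.ndarray) -> list[int]:
    L = len(parent)
    order: list[int] = []
    state = np.zeros(L, dtype=bool)
    for i in range(L):
        chain = []
        j = i
        while not state[j]:
            chain.append(j)
            if parent[j] < 0:
                break
            j = parent[j]
        for node in reversed(chain):
            if not state[node]:
                state[node] = True
                order.append(node)
    return order


def generate_alignment(spec: TreeSpec, N: int,
                       seed: int | np.random.Generator = 0) -> Alignment:
    """Sample N gap-free sequences root-down along the planted forest."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mat = np.empty((N, spec.L), dtype=np.uint8)
    for i in _topological_order(spec.parent):
        p = spec.parent[i]
        if p < 0:
            mat[:, i] = rng.choice(20, size=N, p=spec.root_dist[int(i)])
        else:
            table = spec.cond_tables[i]
            # vectorised row-wise categorical draw via inverse CDF
            cdf = np.cumsum(table[mat[:, p].astype(int)], axis=1)
            u = rng.random(N)[:, None]
            mat[:, i] = (u > cdf).sum(axis=1)
    ids = [f"seq{k}" for k in range(N)]
    return Alignment(ids, mat)


@dataclass
class ScenarioSpec:
    """A planted contact graph with couplings, coordinates and truth labels."""

    n_nodes: int
    contact_edges: list[tuple[int, int, float]]   # (i, j, coupling)
    coords: np.ndarray                             # (n_nodes, 3) Angstrom
    indirect_pairs: list[tuple[int, int]]
    contact_threshold: float = 8.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.n_nodes, 3):
            raise ValueError("coords must be (n_nodes, 3)")
        edge_set = {(min(i, j), max(i, j)) for i, j, _ in self.contact_edges}
        for a, b in self.indirect_pairs:
            if (min(a, b), max(a, b)) in edge_set:
                raise ValueError(f"indirect pair ({a},{b}) is a planted edge")


def fig_scenario() -> ScenarioSpec:
    """The five-residue chain scenario: A-B, B-C strong; D-E weaker; (A, C) distal.

    Coordinates put A-B, B-C and D-E below the 8 Angstrom contact threshold
    and everything else above it.  Couplings (0.9 strong, 0.5 weak) are the
    package's stated world for this construction.
    """
    coords = np.array([
        [0.0, 0.0, 0.0],    # A
        [6.0, 0.0, 0.0],    # B
        [12.0, 0.0, 0.0],   # C: 12 A from A -> distal
        [0.0, 30.0, 0.0],   # D
        [6.0, 30.0, 0.0],   # E
    ])
    return ScenarioSpec(
        n_nodes=5,
        contact_edges=[(0, 1, 0.9), (1, 2, 0.9), (3, 4, 0.5)],
        coords=coords,
        indirect_pairs=[(0, 2)],
    )


def generate_contact_scenario(spec: ScenarioSpec, N: int,
                              seed: int | np.random.Generator = 0):
    """Alignment + toy ContactMap + ground truth from a planted scenario.

    Dependencies follow a spanning forest of the planted contact graph
    (edges taken in listed order, cycle-closing edges skipped); the contact
    map comes from the scenario coordinates at the stated threshold.

    Returns
    -------
    (Alignment, ContactMap, truth) where truth = {"direct_edges": [...],
    "indirect_pairs": [...]}.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = spec.n_nodes
    # spanning forest via union-find over the listed edges
    uf = list(range(L))

    def find(x: int) -> int:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    forest: list[tuple[int, int, float]] = []
    for i, j, c in spec.contact_edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            uf[ri] = rj
            forest.append((i, j, c))
    parent = _orient_edges([(i, j) for i, j, _ in forest], L)
    coupling_of = {}
    for i, j, c in forest:
        child = i if parent[i] == j else j
        coupling_of[child] = c
    root_dist = {int(r): rng.dirichlet(np.ones(20))
                 for r in np.flatnonzero(parent < 0)}
    cond = {child: sample_conditional_tables(c, rng)
            for child, c in coupling_of.items()}
    tree = TreeSpec(L=L, parent=parent, root_dist=root_dist, cond_tables=cond)
    aln = generate_alignment(tree, N, rng)

    diff = spec.coords[:, None, :] - spec.coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    np.fill_diagonal(dist, np.nan)
    dmap = DistanceMap(dist=dist, source_count=np.ones((L, L), dtype=int))
    cmap = build_contact_map(dmap, threshold=spec.contact_threshold)
    truth = {
        "direct_edges": [(min(i, j), max(i, j)) for i, j, _ in spec.contact_edges],
        "indirect_pairs": [(min(a, b), max(a, b)) for a, b in spec.indirect_pairs],
    }
    return aln, cmap, truth
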