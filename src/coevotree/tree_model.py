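"""Spanning-tree Bayesian network: tree sums, evidence, edge posteriors, MST.

The model sums the likelihood of the alignment over all L^(L-2) labelled
dependence trees.  Writing beta_ij for the weight of edge (i, j) — the pair's
R value, possibly raised to a power alpha and multiplied by an informative
prior weight — the sum over trees of the product of edge weights is a single
cofactor determinant of the graph Laplacian (weighted matrix-tree theorem).
The posterior probability that a particular edge is in the (unknown) tree is
the weighted fraction of spanning trees containing it.

Two equivalent routes compute the posteriors:

``resistance`` (default)
    P(ij | D) = beta_ij * R_eff(i, j), where R_eff is the effective
    resistance between i and j in the graph with conductances beta.  One
    reduced-Laplacian inverse gives all pairs, O(L^3) total.

``contraction``
    Contract i and j into a single node (weights to any other node l become
    beta_il + beta_jl), compute the contracted graph's tree sum as a
    determinant, multiply by beta_ij and divide by the full tree sum.  One
    determinant per pair; slower but works entirely in the log domain and
    serves as an internal cross-check.

Because every spanning tree has exactly L-1 edges, all posteriors are exactly
invariant under a global rescaling of beta; internally the maximum log-weight
is always factored out before exponentiation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from coevotree.msa_io import Alignment, column_counts
from coevotree.pair_stats import DirichletParams, ScoreMatrix, log_marginal_prob

__all__ = [
    "BetaMatrix", "PosteriorMatrix", "build_beta", "rescale_beta",
    "spanning_tree_sum", "log_evidence", "edge_posteriors",
    "max_spanning_tree", "write_posterior_tsv",
]


@dataclass
class BetaMatrix:
    """Symmetric positive edge weights, held in the log domain.

    ``log_beta`` is L x L with an ignored diagonal; ``rescaled`` marks
    matrices already mapped into [lambda_min, 1].
    """

    log_beta: np.ndarray
    rescaled: bool = False

    def __post_init__(self):
        lb = np.asarray(self.log_beta, dtype=float)
        if lb.ndim != 2 or lb.shape[0] != lb.shape[1]:
            raise ValueError("log_beta must be square")
        offdiag = ~np.eye(lb.shape[0], dtype=bool)
        if not np.allclose(lb[offdiag], lb.T[offdiag], equal_nan=True):
            raise ValueError("log_beta must be symmetric")
        self.log_beta = lb

    @property
    def n_cols(self) -> int:
        return self.log_beta.shape[0]

    @property
    def beta(self) -> np.ndarray:
        b = np.exp(self.log_beta)
        np.fill_diagonal(b, 0.0)
        return b


@dataclass
class PosteriorMatrix:
    """Posterior edge probabilities P(ij | D); they sum to L-1 over i<j."""

    post: np.ndarray
    log_tree_sum: float

    @property
    def n_cols(self) -> int:
        return self.post.shape[0]

    def total(self) -> float:
        iu = np.triu_indices(self.n_cols, k=1)
        return float(np.nansum(self.post[iu]))


def build_beta(scores: ScoreMatrix, prior_weights: np.ndarray | None = None,
               alpha: float = 1.0) -> BetaMatrix:
    """Edge weights log beta_ij = alpha * score_ij + log w_ij.

    With a uniform tree prior (``prior_weights=None``, all w = 1) and
    alpha = 1, beta reduces to R.  alpha < 1 discounts the score, modelling
    the fact that phylogenetically related sequences carry fewer than N
    independent observations; alpha = 0 uses only the prior.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    lb = alpha * np.asarray(scores.values, dtype=float)
    if prior_weights is not None:
        w = np.asarray(prior_weights, dtype=float)
        if w.shape != lb.shape:
            raise ValueError("prior weight matrix shape mismatch")
        with np.errstate(divide="ignore"):
            lb = lb + np.log(w)
    np.fill_diagonal(lb, -np.inf)
    return BetaMatrix(lb)


def rescale_beta(b: BetaMatrix, lambda_min: float = 1e-12) -> BetaMatrix:
    """Affinely map log weights so beta spans [lambda_min, 1].

    Raw beta values vary over hundreds of orders of magnitude, which makes
    the Laplacian determinant numerically hopeless.  The map

        beta' = exp( log(lambda_min) * (Lmax - log beta) / (Lmax - Lmin) )

    sends the maximal entry to 1 and the minimal entry to lambda_min, is
    strictly increasing, and does not exaggerate relative differences.  It is
    an order-preserving *approximation*: posteriors computed from rescaled
    weights differ from those of the raw weights.
    """
    if not (0.0 < lambda_min < 1.0):
        raise ValueError("lambda_min must be in (0, 1)")
    lb = b.log_beta.copy()
    offdiag = ~np.eye(b.n_cols, dtype=bool)
    vals = lb[offdiag]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite edge weights to rescale")
    lmax, lmin = float(vals.max()), float(vals.min())
    out = np.zeros_like(lb)
    if lmax == lmin:
        out[offdiag] = 0.0  # all beta' = 1
    else:
        out[offdiag] = np.log(lambda_min) * (lmax - lb[offdiag]) / (lmax - lmin)
    np.fill_diagonal(out, -np.inf)
    return BetaMatrix(out, rescaled=True)


def _weights(b: BetaMatrix) -> tuple[np.ndarray, float]:
    """Exponentiated weights with the max log-weight factored out (returned)."""
    lb = b.log_beta
    offdiag = ~np.eye(b.n_cols, dtype=bool)
    finite = lb[offdiag][np.isfinite(lb[offdiag])]
    shift = float(finite.max()) if finite.size else 0.0
    w = np.exp(lb - shift)
    np.fill_diagonal(w, 0.0)
    return w, shift


def _log_tree_sum_from_weights(w: np.ndarray, drop: int = 0) -> float:
    """log det of the Laplacian cofactor of a weight matrix (log tree sum)."""
    lap = np.diag(w.sum(axis=1)) - w
    minor = np.delete(np.delete(lap, drop, axis=0), drop, axis=1)
    if minor.size == 0:  # L = 1: empty product convention
        return 0.0
    sign, logdet = np.linalg.slogdet(minor)
    if sign <= 0:
        warnings.warn("singular or indefinite Laplacian minor: graph is "
                      "effectively disconnected")
        return -np.inf
    return float(logdet)


def spanning_tree_sum(b: BetaMatrix, drop: int = 0) -> float:
    """log of sum over all spanning trees T of prod_{(ij) in T} beta_ij.

    Computed as the log-determinant of the Laplacian with row and column
    ``drop`` removed (matrix-tree theorem); the result is independent of
    which index is dropped.
    """
    if b.n_cols < 2:
        raise ValueError("need at least 2 columns")
    w, shift = _weights(b)
    ld = _log_tree_sum_from_weights(w, drop=drop)
    return ld + (b.n_cols - 1) * shift


def log_evidence(a: Alignment, b: BetaMatrix,
                 params: DirichletParams | None = None) -> float:
    """Log marginal likelihood of the alignment under the tree mixture.

    Sum of the single-column log marginals, plus the log spanning-tree sum of
    beta, plus the normalisation of the uniform tree prior, -(L-2) log L.
    Meaningful only for raw (non-rescaled) beta.
    """
    if params is None:
        params = DirichletParams()
    if b.rescaled:
        warnings.warn("log_evidence on rescaled beta is not a true likelihood")
    L = a.n_cols
    cols = sum(log_marginal_prob(column_counts(a, i), params) for i in range(L))
    if L == 1:
        return cols
    return cols + spanning_tree_sum(b) - (L - 2) * np.log(L)


def edge_posteriors(b: BetaMatrix, method: str = "resistance") -> PosteriorMatrix:
    """Posterior probability of each edge appearing in the dependence tree."""
    L = b.n_cols
    if L < 2:
        raise ValueError("need at least 2 columns")
    w, shift = _weights(b)
    log_full = _log_tree_sum_from_weights(w)
    if method == "resistance":
        post = _posteriors_resistance(w, log_full)
    elif method == "contraction":
        post = _posteriors_contraction(w, log_full)
    else:
        raise ValueError(f"unknown posterior method {method!r}")
    np.fill_diagonal(post, np.nan)
    return PosteriorMatrix(post=post, log_tree_sum=log_full + (L - 1) * shift)


def _posteriors_resistance(w: np.ndarray, log_full: float) -> np.ndarray:
    """All posteriors from one reduced-Laplacian inverse.

    In a random spanning tree drawn proportionally to its weight product, the
    probability that edge (i, j) appears equals w_ij times the effective
    resistance between i and j.
    """
    L = w.shape[0]
    if not np.isfinite(log_full):
        return np.zeros((L, L))
    lap = np.diag(w.sum(axis=1)) - w
    minv = np.linalg.inv(lap[1:, 1:])
    d = np.diag(minv)
    reff = np.empty((L, L))
    reff[1:, 1:] = d[:, None] + d[None, :] - minv - minv.T
    reff[0, 1:] = reff[1:, 0] = d
    reff[0, 0] = 0.0
    post = w * reff
    return np.clip(post, 0.0, 1.0)


def _posteriors_contraction(w: np.ndarray, log_full: float) -> np.ndarray:
    """Posteriors by contracting each pair and re-applying the matrix-tree
    theorem; one (L-2)-sized determinant per pair, fully in the log domain."""
    L = w.shape[0]
    post = np.zeros((L, L))
    if not np.isfinite(log_full):
        return post
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    for i in range(L):
        for j in range(i + 1, L):
            if w[i, j] == 0.0:
                continue
            others = [k for k in range(L) if k not in (i, j)]
            wc = np.empty((L - 1, L - 1))
            sub = w[np.ix_(others, others)]
            wc[:-1, :-1] = sub
            merged = w[i, others] + w[j, others]
            wc[-1, :-1] = merged
            wc[:-1, -1] = merged
            wc[-1, -1] = 0.0
            log_contracted = _log_tree_sum_from_weights(wc)
            lp = log_contracted + logw[i, j] - log_full
            post[i, j] = post[j, i] = np.exp(min(lp, 0.0))
    return post


def max_spanning_tree(b: BetaMatrix) -> list[tuple[int, int]]:
    """Maximum spanning tree of the log-weights (Chow-Liu tree).

    Kruskal with deterministic tie-breaking: edges sorted by descending
    weight, then lexicographically by (i, j).  Returns L-1 edges as (i, j)
    with i < j.
    """
    L = b.n_cols
    if L < 2:
        raise ValueError("need at least 2 columns")
    edges = sorted(
        ((i, j) for i in range(L) for j in range(i + 1, L)),
        key=lambda e: (-b.log_beta[e[0], e[1]], e[0], e[1]),
    )
    parent = list(range(L))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree: list[tuple[int, int]] = []
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j))
            if len(tree) == L - 1:
                break
    return tree


def write_posterior_tsv(pm: PosteriorMatrix, path) -> None:
    """Write posteriors as ``col_i  col_j  posterior``, sorted descending."""
    L = pm.n_cols
    rows = [
        (i, j, pm.post[i, j])
        for i in range(L) for j in range(i + 1, L)
        if not np.isnan(pm.post[i, j])
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(f"# log_tree_sum={pm.log_tree_sum:.10g}\n# col_i\tcol_j\tposterior\n")
        for i, j, p in rows:
            fh.write(f"{i}\t{j}\t{p:.10g}\n")
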