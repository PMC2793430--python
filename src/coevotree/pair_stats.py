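"""Pairwise column statistics: Dirichlet-marginal likelihoods, log R, MI, Z, APC.

The central quantity is the finite-size-corrected dependency measure

    log R_ij = log P(n_ab) - log P(n_a) - log P(n_b),

the log ratio of the Dirichlet-multinomial marginal likelihood of the joint
amino-acid counts of two columns to the product of the column marginals.  For
large N, log R / N converges to the plug-in mutual information of the pair
(Stirling's approximation), but unlike MI it penalises the extra complexity
of the joint model, so independent columns score negative.

Counting convention: for a pair (i, j), sequences with a gap at either
position are discarded entirely, and the single-column marginal counts are
recomputed on the same gap-filtered subset, so that R is a coherent
likelihood ratio.  Treating gaps as a 21st letter would create strong
spurious couplings between nearby columns because gaps come in blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from coevotree.msa_io import GAP, Alignment, column_counts

__all__ = [
    "DirichletParams", "PairCounts", "ScoreMatrix",
    "pair_counts", "log_marginal_prob", "log_joint_prob", "log_R",
    "score_matrix", "mutual_information", "column_entropy",
    "z_transform", "apc_correct", "asc_correct",
    "write_score_tsv", "read_score_tsv",
]


@dataclass
class DirichletParams:
    """Pseudocounts of the Dirichlet priors over single and joint columns.

    Consistency of the dependence-tree model requires the joint (400-cell)
    pseudocount to be the single-column (20-cell) pseudocount divided by 20,
    so ``lambda_pair`` is derived unless given explicitly — in which case the
    constraint is checked.
    """

    lambda_single: float = 0.5
    lambda_pair: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.lambda_single <= 0:
            raise ValueError("lambda_single must be positive")
        if self.lambda_pair is None:
            self.lambda_pair = self.lambda_single / 20.0
        elif not np.isclose(self.lambda_pair, self.lambda_single / 20.0):
            raise ValueError("consistency requires lambda_pair = lambda_single / 20")


@dataclass
class PairCounts:
    """Joint counts for a column pair on the gap-filtered sequence subset."""

    n_ab: np.ndarray  # (20, 20)
    n_a: np.ndarray   # (20,) row marginal
    n_b: np.ndarray   # (20,) column marginal
    n: int            # retained sequences


class NoUsableSequences(ValueError):
    """Every sequence has a gap at one of the two positions."""


@dataclass
class ScoreMatrix:
    """Symmetric L x L pair-score matrix; the diagonal is undefined (NaN).

    ``kind`` is one of ``logR``, ``logR_shifted``, ``logR_apc``, ``mi``,
    ``asc``, ``z``.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("score matrix must be square")
        self.values = v

    @property
    def n_cols(self) -> int:
        return self.values.shape[0]

    def defined_offdiag(self) -> np.ndarray:
        """Values of the defined off-diagonal entries (upper triangle)."""
        iu = np.triu_indices(self.n_cols, k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]


def pair_counts(a: Alignment, i: int, j: int) -> PairCounts:
    """Joint 20x20 counts of columns (i, j), dropping sequences gapped at either."""
    if i == j:
        raise ValueError("pair_counts requires two distinct columns")
    ci, cj = a.matrix[:, i], a.matrix[:, j]
    keep = (ci < GAP) & (cj < GAP)
    xi, xj = ci[keep].astype(np.int64), cj[keep].astype(np.int64)
    n = int(keep.sum())
    if n == 0:
        raise NoUsableSequences(f"no usable sequences for pair ({i}, {j})")
    n_ab = np.bincount(20 * xi + xj, minlength=400).reshape(20, 20).astype(np.int64)
    return PairCounts(n_ab=n_ab, n_a=n_ab.sum(axis=1), n_b=n_ab.sum(axis=0), n=n)


def log_marginal_prob(counts: np.ndarray, params: DirichletParams) -> float:
    """Log Dirichlet-multinomial marginal of a 20-cell count vector.

    log[ Gamma(20 lam) / Gamma(N + 20 lam) * prod_a Gamma(n_a + lam)/Gamma(lam) ]
    """
    return _log_dirmult(np.asarray(counts, dtype=float).ravel(), params.lambda_single)


def log_joint_prob(pc: PairCounts, params: DirichletParams) -> float:
    """Log Dirichlet-multinomial marginal of the 400-cell joint counts."""
    return _log_dirmult(pc.n_ab.astype(float).ravel(), params.lambda_pair)


def _log_dirmult(counts: np.ndarray, lam: float) -> float:
    if lam <= 0:
        raise ValueError("Dirichlet parameter must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    k = counts.size
    n = counts.sum()
    pos = counts > 0
    return float(
        gammaln(k * lam) - gammaln(n + k * lam)
        + np.sum(gammaln(counts[pos] + lam)) - pos.sum() * gammaln(lam)
    )


def log_R(a: Alignment, i: int, j: int, params: DirichletParams | None = None) -> float:
    """Finite-size-corrected dependency of columns (i, j) in nats."""
    if params is None:
        params = DirichletParams()
    pc = pair_counts(a, i, j)
    return (
        log_joint_prob(pc, params)
        - _log_dirmult(pc.n_a.astype(float), params.lambda_single)
        - _log_dirmult(pc.n_b.astype(float), params.lambda_single)
    )


def mutual_information(pc: PairCounts) -> float:
    """Plug-in mutual information (nats) of the empirical joint frequencies."""
    if pc.n <= 0:
        raise ValueError("mutual information needs at least one sequence")
    p = pc.n_ab / pc.n
    pa = pc.n_a / pc.n
    pb = pc.n_b / pc.n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p > 0, p / np.outer(pa, pb), 1.0)
        terms = np.where(p > 0, p * np.log(ratio), 0.0)
    return float(terms.sum())


def column_entropy(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of a column's amino-acid frequencies."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("empty column")
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def score_matrix(a: Alignment, params: DirichletParams | None = None,
                 kind: str = "logR") -> ScoreMatrix:
    """All-pairs score matrix of an alignment (kinds: ``logR`` or ``mi``).

    Pairs with no gap-free sequence are left NaN.
    """
    if params is None:
        params = DirichletParams()
    if kind not in {"logR", "mi"}:
        raise ValueError("score_matrix computes 'logR' or 'mi'")
    L = a.n_cols
    vals = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i + 1, L):
            try:
                pc = pair_counts(a, i, j)
            except NoUsableSequences:
                continue
            if kind == "logR":
                v = (
                    log_joint_prob(pc, params)
                    - _log_dirmult(pc.n_a.astype(float), params.lambda_single)
                    - _log_dirmult(pc.n_b.astype(float), params.lambda_single)
                )
            else:
                v = mutual_information(pc)
            vals[i, j] = vals[j, i] = v
    return ScoreMatrix(vals, kind)


def z_transform(m: ScoreMatrix) -> ScoreMatrix:
    """Standardise a score matrix to Z-values within the alignment.

    Z is the number of population standard deviations from the mean, taken
    over all defined off-diagonal entries.  A degenerate (constant) matrix
    maps to all-zero Z with a warning.
    """
    vals = m.defined_offdiag()
    if vals.size < 2:
        raise ValueError("z_transform needs at least 2 defined entries")
    mean = vals.mean()
    sd = vals.std()  # population SD
    out = np.full_like(m.values, np.nan)
    defined = ~np.isnan(m.values)
    np.fill_diagonal(defined, False)
    if sd == 0:
        warnings.warn("constant score matrix: all Z set to 0")
        out[defined] = 0.0
    else:
        out[defined] = (m.values[defined] - mean) / sd
    return ScoreMatrix(out, "z")


def _row_means(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Off-diagonal row means (over defined partners) and the overall mean."""
    v = values.copy()
    np.fill_diagonal(v, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        row = np.nanmean(v, axis=1)
    iu = np.triu_indices(v.shape[0], k=1)
    off = v[iu]
    overall = float(np.nanmean(off)) if np.any(~np.isnan(off)) else np.nan
    return row, overall


def apc_correct(m: ScoreMatrix) -> ScoreMatrix:
    """Average-product correction adapted to log R.

    MI is non-negative and zero for independent columns, whereas log R is
    negative there and only defined up to a global shift (posteriors are
    shift-invariant).  We therefore first shift the matrix so its minimum is
    exactly zero, then subtract the product correction
    ``rowmean_i * rowmean_j / overallmean`` computed on the shifted entries
    (row means over the L-1 defined partners, overall mean over all defined
    off-diagonal pairs).
    """
    if m.n_cols < 2:
        raise ValueError("APC needs at least 2 columns")
    defined = ~np.isnan(m.values)
    np.fill_diagonal(defined, False)
    shifted = m.values - np.nanmin(m.values[defined]) if defined.any() else m.values
    row, overall = _row_means(shifted)
    out = np.full_like(m.values, np.nan)
    if overall == 0 or np.isnan(overall):
        out[defined] = 0.0
    else:
        corr = np.outer(row, row) / overall
        out[defined] = shifted[defined] - corr[defined]
    return ScoreMatrix(out, "logR_apc")


def asc_correct(m: ScoreMatrix) -> ScoreMatrix:
    """Average-sum correction: ``x_ij - (rowmean_i + rowmean_j - overallmean)``."""
    if m.n_cols < 2:
        raise ValueError("ASC needs at least 2 columns")
    defined = ~np.isnan(m.values)
    np.fill_diagonal(defined, False)
    row, overall = _row_means(m.values)
    out = np.full_like(m.values, np.nan)
    corr = row[:, None] + row[None, :] - overall
    out[defined] = m.values[defined] - corr[defined]
    return ScoreMatrix(out, "asc")


def write_score_tsv(m: ScoreMatrix, path) -> None:
    """Serialize defined off-diagonal entries as ``col_i  col_j  value``."""
    with open(path, "w") as fh:
        fh.write(f"# kind={m.kind}\n# col_i\tcol_j\tvalue\n")
        L = m.n_cols
        for i in range(L):
            for j in range(i + 1, L):
                if not np.isnan(m.values[i, j]):
                    fh.write(f"{i}\t{j}\t{m.values[i, j]:.10g}\n")


def read_score_tsv(path) -> ScoreMatrix:
    kind = "logR"
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "kind=" in line:
                    kind = line.split("kind=")[1].split()[0]
                continue
            if line:
                i, j, v = line.split("\t")
                entries.append((int(i), int(j), float(v)))
    L = max(max(i, j) for i, j, _ in entries) + 1 if entries else 0
    vals = np.full((L, L), np.nan)
    for i, j, v in entries:
        vals[i, j] = vals[j, i] = v
    return ScoreMatrix(vals, kind)
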