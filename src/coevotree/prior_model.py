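"""Informative edge prior from sequence separation and column conservation.

The probability that a pair of columns is in structural contact depends
strongly on (i) their primary-sequence separation d and (ii) how conserved
the two columns are, summarised by the sum h of their entropies.  The prior
factorises as

    f(d, h) = F(d)            for d <= d_switch (short range: entropy-free)
    f(d, h) = g(h) * F(d)     for d >  d_switch

where F(d) is the overall contact fraction at separation d — tabulated
empirically up to a cutoff D and extended beyond D by a power-law tail
c * d^(-gamma) made continuous at D — and g(h) is a per-entropy-bin factor
fitted by maximum likelihood.

To turn f into a prior over spanning trees we use a random-graph model in
which edge (i, j) occurs independently with probability p_ij proportional to
f(d_ij, h_ij), normalised so that the expected number of edges equals the
L - 1 edges of a tree.  Dividing by the probability of the empty graph, the
prior probability of a tree is (up to a constant) the product over its edges
of w_ij = p_ij / (1 - p_ij); these w feed the tree model's edge weights.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "PriorModel", "EdgePriorMatrix",
    "estimate_contact_fraction", "estimate_entropy_factor",
    "edge_prior_matrix", "save_prior", "load_prior", "fit_prior",
]

_SCHEMA_VERSION = 1
_P_CAP = 1.0 - 1e-9


@dataclass
class PriorModel:
    """Fitted separation profile F(d), entropy factor g(h), and blend weight.

    Attributes
    ----------
    F_table : dict[int, float]
        Empirical contact fraction per separation, for d <= D.
    D : int
        Last tabulated separation; beyond it F follows ``c * d**-gamma``.
    c, gamma : float
        Power-law tail, with c fixed by continuity at D.
    g_centers, g_values : arrays
        Entropy-bin centers (bin width ``bin_width``) and fitted factors.
    d_switch : int
        Separation at or below which f(d, h) = F(d), entropy-independent.
    alpha : float
        Blend weight between data scores and prior in the tree model.
    """

    F_table: dict[int, float]
    D: int
    c: float
    gamma: float
    g_centers: np.ndarray
    g_values: np.ndarray
    bin_width: float
    d_switch: int = 4
    alpha: float = 0.1

    def __post_init__(self):
        self.g_centers = np.asarray(self.g_centers, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        if self.g_centers.shape != self.g_values.shape:
            raise ValueError("g table centers/values mismatch")

    def F(self, d) -> np.ndarray:
        """Contact fraction vs separation (vectorised)."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        out = np.empty_like(d)
        tail = d > self.D
        with np.errstate(divide="ignore"):
            out[tail] = self.c * d[tail] ** (-self.gamma)
        out[~tail] = [self.F_table.get(int(x), np.nan) for x in d[~tail]]
        return out

    def g(self, h) -> np.ndarray:
        """Entropy factor, nearest-bin lookup (vectorised)."""
        h = np.atleast_1d(np.asarray(h, dtype=float))
        idx = np.abs(h[:, None] - self.g_centers[None, :]).argmin(axis=1)
        return self.g_values[idx]

    def f(self, d, h) -> np.ndarray:
        """Joint contact probability f(d, h), clipped to [0, 1)."""
        d = np.atleast_1d(np.asarray(d, dtype=float))
        h = np.atleast_1d(np.asarray(h, dtype=float))
        base = self.F(d)
        out = np.where(d <= self.d_switch, base, self.g(h) * base)
        return np.clip(out, 0.0, _P_CAP)


@dataclass
class EdgePriorMatrix:
    """Per-edge occurrence probabilities p (summing to L-1) and weights p/(1-p)."""

    p: np.ndarray
    w: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.w is None:
            with np.errstate(divide="ignore", invalid="ignore"):
                self.w = np.where(np.isnan(self.p), np.nan, self.p / (1.0 - self.p))


def estimate_contact_fraction(pairs, D: int = 14, gamma: float = 1.0):
    """Empirical F(d) up to D plus a continuous power-law tail.

    Parameters
    ----------
    pairs : iterable of (d, is_contact)
        Separation (positive int) and boolean contact label per pair.
    D : int
        Cutoff separation: empirical fractions are tabulated for d <= D, and
        the tail ``c * d**-gamma`` (c from continuity at D) is used beyond.
    gamma : float
        Tail exponent; the observed decay is approximately 1/d.

    Returns
    -------
    (F_table, c, gamma)
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs given")
    d_arr = np.array([int(p[0]) for p in pairs])
    y_arr = np.array([bool(p[1]) for p in pairs])
    F_table: dict[int, float] = {}
    for d in range(1, D + 1):
        sel = d_arr == d
        if sel.any():
            F_table[d] = float(y_arr[sel].mean())
    if D not in F_table:
        raise ValueError(f"no pairs at the cutoff separation D={D}; "
                         "cannot anchor the power-law tail")
    c = F_table[D] * D ** gamma
    return F_table, c, gamma


def _fit_g_bin(F_vals: np.ndarray, labels: np.ndarray) -> float:
    """MLE of g for one entropy bin under Bernoulli(g * F(d_e)) labels."""
    if not labels.any():
        return 0.0
    g_hi = _P_CAP / float(F_vals.max())

    def nll(g: float) -> float:
        p = np.clip(g * F_vals, 1e-300, _P_CAP)
        return -(np.log(p)[labels].sum() + np.log1p(-p)[~labels].sum())

    res = minimize_scalar(nll, bounds=(1e-12, g_hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def estimate_entropy_factor(pairs, model_F, d_switch: int = 4,
                            bin_width: float = 0.25):
    """Per-entropy-bin factors g(h) by maximum likelihood.

    Only pairs with d > d_switch enter (short-range contacts are entropy-
    independent by construction).  Bins spanning the observed entropy range
    with the given width; an empty interior bin is linearly interpolated from
    its neighbours (logged).

    Parameters
    ----------
    pairs : iterable of (d, h, is_contact)
    model_F : callable d -> F(d)  (e.g. ``PriorModel.F`` or a closure)
    """
    rows = [(int(d), float(h), bool(y)) for d, h, y in pairs if d > d_switch]
    if not rows:
        raise ValueError("no pairs beyond d_switch")
    d_arr = np.array([r[0] for r in rows])
    h_arr = np.array([r[1] for r in rows])
    y_arr = np.array([r[2] for r in rows])
    F_vals = np.asarray(model_F(d_arr), dtype=float)
    ok = np.isfinite(F_vals) & (F_vals > 0)
    d_arr, h_arr, y_arr, F_vals = d_arr[ok], h_arr[ok], y_arr[ok], F_vals[ok]

    lo = np.floor(h_arr.min() / bin_width) * bin_width
    hi = np.ceil(h_arr.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    centers = (edges[:-1] + edges[1:]) / 2
    idx = np.clip(np.digitize(h_arr, edges) - 1, 0, centers.size - 1)

    g = np.full(centers.size, np.nan)
    for b in range(centers.size):
        sel = idx == b
        if sel.any():
            g[b] = _fit_g_bin(F_vals[sel], y_arr[sel])
    missing = np.isnan(g)
    if missing.any():
        logger.info("interpolating %d empty entropy bins", int(missing.sum()))
        g[missing] = np.interp(centers[missing], centers[~missing], g[~missing])
    return centers, g


def fit_prior(pairs, D: int = 14, gamma: float = 1.0, d_switch: int = 4,
              bin_width: float = 0.25, alpha: float = 0.1) -> PriorModel:
    """Fit the full prior model from (d, h, is_contact) triples."""
    F_table, c, gamma = estimate_contact_fraction(
        [(d, y) for d, _, y in pairs], D=D, gamma=gamma)

    def F_fn(d):
        d = np.asarray(d, dtype=float)
        out = np.where(d > D, c * np.where(d > 0, d, 1.0) ** (-gamma), 0.0)
        small = d <= D
        out = out.astype(float)
        out[small] = [F_table.get(int(x), np.nan) for x in d[small]]
        return out

    centers, g = estimate_entropy_factor(pairs, F_fn, d_switch=d_switch,
                                         bin_width=bin_width)
    return PriorModel(F_table=F_table, D=D, c=c, gamma=gamma,
                      g_centers=centers, g_values=g,
                      bin_width=bin_width, d_switch=d_switch, alpha=alpha)


def edge_prior_matrix(sep: np.ndarray, entropy: np.ndarray,
                      model: PriorModel) -> EdgePriorMatrix:
    """Edge occurrence probabilities p_ij for one domain.

    p_ij is proportional to f(d_ij, h_i + h_j) and normalised so that the
    expected number of edges, sum over i<j of p_ij, equals L - 1 (the edge
    count of any spanning tree).  Probabilities that would reach 1 are capped
    just below it and the remaining mass re-normalised over the free pairs.
    """
    sep = np.asarray(sep, dtype=float)
    L = sep.shape[0]
    if L < 2:
        raise ValueError("need at least 2 columns")
    h = np.asarray(entropy, dtype=float)
    hsum = h[:, None] + h[None, :]
    iu = np.triu_indices(L, k=1)
    f = model.f(sep[iu], hsum[iu])
    if not np.any(f > 0):
        raise ValueError("prior assigns zero probability to every edge")

    target = float(L - 1)
    p = f * (target / f.sum())
    # cap-and-renormalise: keep sum = L-1 while every p < 1
    for _ in range(100):
        over = p >= _P_CAP
        if not over.any():
            break
        free = ~over
        deficit = target - _P_CAP * over.sum()
        if deficit <= 0 or not free.any() or p[free].sum() == 0:
            p[over] = _P_CAP
            break
        p[free] *= deficit / p[free].sum()
        p[over] = _P_CAP
        if (p[free] < _P_CAP).all():
            break

    mat = np.full((L, L), np.nan)
    mat[iu] = p
    mat.T[iu] = p
    return EdgePriorMatrix(p=mat)


def save_prior(model: PriorModel, path) -> None:
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "F_table": {str(k): v for k, v in model.F_table.items()},
        "D": model.D,
        "c": model.c,
        "gamma": model.gamma,
        "g_centers": model.g_centers.tolist(),
        "g_values": model.g_values.tolist(),
        "bin_width": model.bin_width,
        "d_switch": model.d_switch,
        "alpha": model.alpha,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


class PriorSchemaError(ValueError):
    """Malformed or version-incompatible prior document."""


def load_prior(path) -> PriorModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise PriorSchemaError(
            f"unsupported prior schema version {doc.get('schema_version')!r}")
    required = {"F_table", "D", "c", "gamma", "g_centers", "g_values",
                "bin_width", "d_switch", "alpha"}
    missing = required - doc.keys()
    if missing:
        raise PriorSchemaError(f"missing prior fields: {sorted(missing)}")
    return PriorModel(
        F_table={int(k): float(v) for k, v in doc["F_table"].items()},
        D=int(doc["D"]), c=float(doc["c"]), gamma=float(doc["gamma"]),
        g_centers=np.array(doc["g_centers"], dtype=float),
        g_values=np.array(doc["g_values"], dtype=float),
        bin_width=float(doc["bin_width"]), d_switch=int(doc["d_switch"]),
        alpha=float(doc["alpha"]),
    )
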