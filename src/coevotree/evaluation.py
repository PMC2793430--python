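"""Scoring contact predictions: PPV at fixed sensitivity or rank, binned stats.

PPV (positive predictive value) is the fraction of predicted pairs that are
true contacts; sensitivity is the fraction of all true contacts predicted.
Rankings are deterministic: stable sort on descending score with pair-index
tie-break, so curves are bit-for-bit reproducible.  Pairs whose contact
status is undefined (no structure coverage) are excluded from numerator and
denominator alike, and a minimum-separation filter can restrict the pair
universe (the conventional panels use all, >=3, >=12 and >=24 positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coevotree.pair_stats import ScoreMatrix
from coevotree.structure_contacts import ContactMap

__all__ = ["PredictionSet", "ppv_at_sensitivity", "ppv_at_rank",
           "bin_statistic", "aggregate_ppv"]


@dataclass
class PredictionSet:
    """A ranked list of pair predictions for one domain."""

    pairs: list[tuple[int, int]]   # (i, j) with i < j, best first
    scores: np.ndarray
    min_separation: int = 0
    domain_id: str = ""

    @classmethod
    def from_matrix(cls, m: ScoreMatrix, cm: ContactMap | None = None,
                    min_separation: int = 0,
                    domain_id: str = "") -> "PredictionSet":
        """Rank all defined pairs of a score matrix, applying the separation
        filter (and dropping pairs with undefined contact status if a map is
        given)."""
        L = m.n_cols
        entries = []
        for i in range(L):
            for j in range(i + 1, L):
                v = m.values[i, j]
                if np.isnan(v):
                    continue
                if cm is not None:
                    if np.isnan(cm.contact[i, j]):
                        continue
                    if cm.sep[i, j] < min_separation:
                        continue
                elif (j - i) < min_separation:
                    continue
                entries.append((i, j, float(v)))
        entries.sort(key=lambda e: (-e[2], e[0], e[1]))
        return cls(pairs=[(i, j) for i, j, _ in entries],
                   scores=np.array([v for _, _, v in entries]),
                   min_separation=min_separation, domain_id=domain_id)


def _truth_vector(pred: PredictionSet, cm: ContactMap) -> np.ndarray:
    truth = np.array([cm.contact[i, j] for i, j in pred.pairs])
    if np.isnan(truth).any():
        keep = ~np.isnan(truth)
        truth = truth[keep]
    return truth.astype(bool)


def ppv_at_sensitivity(pred: PredictionSet, cm: ContactMap,
                       fractions) -> list[tuple[float, float, float]]:
    """(requested sensitivity, achieved sensitivity, PPV) per fraction.

    For each requested sensitivity f, the smallest top-k is taken whose true
    positives cover at least a fraction f of all true contacts in the
    filtered universe, and PPV = TP(k) / k is reported.
    """
    truth = _truth_vector(pred, cm)
    n_contacts = int(truth.sum())
    if n_contacts == 0:
        raise ValueError("no true contacts in the filtered pair universe")
    tp_cum = np.cumsum(truth)
    out = []
    for f in fractions:
        if not (0.0 < f <= 1.0):
            raise ValueError("sensitivity fractions must lie in (0, 1]")
        target = f * n_contacts
        k = int(np.searchsorted(tp_cum, target - 1e-12) + 1)
        k = min(k, len(truth))
        sens = tp_cum[k - 1] / n_contacts
        out.append((float(f), float(sens), float(tp_cum[k - 1] / k)))
    return out


def ppv_at_rank(pred: PredictionSet, cm: ContactMap,
                ranks) -> list[tuple[int, float]]:
    """(rank, PPV of the top-rank predictions) per requested cutoff."""
    truth = _truth_vector(pred, cm)
    tp_cum = np.cumsum(truth)
    out = []
    for r in ranks:
        if r < 1:
            raise ValueError("ranks must be >= 1")
        k = min(int(r), len(truth))
        out.append((int(r), float(tp_cum[k - 1] / k)))
    return out


def aggregate_ppv(per_domain: list[list[tuple[float, float, float]]]):
    """Average PPV across domains at each fixed sensitivity, with standard error.

    All domains must have been evaluated on the same sensitivity grid.
    Returns (fractions, mean PPV, standard error).
    """
    if not per_domain:
        raise ValueError("no domains")
    fracs = [f for f, _, _ in per_domain[0]]
    mat = np.array([[p for _, _, p in dom] for dom in per_domain])
    mean = mat.mean(axis=0)
    se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
        else np.zeros(mat.shape[1])
    return np.array(fracs), mean, se


def bin_statistic(x, y, bin_edges, percentiles=(25, 50, 75)):
    """Per-bin percentiles and means of y grouped by binned x.

    Percentiles use linear interpolation.  Returns a list of dicts, one per
    bin, with NaN statistics for empty bins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for b in range(len(edges) - 1):
        if b < len(edges) - 2:
            sel = (x >= edges[b]) & (x < edges[b + 1])
        else:
            sel = (x >= edges[b]) & (x <= edges[b + 1])  # closed last bin
        row = {"bin_lo": float(edges[b]), "bin_hi": float(edges[b + 1]),
               "count": int(sel.sum())}
        if sel.any():
            yy = y[sel]
            row["mean"] = float(yy.mean())
            for p in percentiles:
                row[f"p{p}"] = float(np.percentile(yy, p))
        else:
            row["mean"] = np.nan
            for p in percentiles:
                row[f"p{p}"] = np.nan
        rows.append(row)
    return rows
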