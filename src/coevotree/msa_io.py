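"""Reading, validation and preprocessing of protein multiple sequence alignments.

Alignments are stored as an integer matrix over the 20 standard amino acids
plus gap.  Columns are indexed by *match states*: for Pfam-style Stockholm
files only the match columns (``#=GC RF`` annotation, or the upper-case /
``-`` convention) are retained, and ``col_origin`` remembers each retained
column's 1-based position in the original alignment so that primary-sequence
separations can be reported in match-state units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import AlignIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = 20  # integer code for a gap
GAP_CHARS = frozenset(".-~")
#: non-standard residue codes mapped to gap by default (the model's alphabet
#: is exactly the 20 standard amino acids)
AMBIGUOUS_CODES = frozenset("BZXUOJ")


class AlignmentFormatError(ValueError):
    """Raised when an input alignment cannot be parsed or has ragged rows."""


class AlphabetError(ValueError):
    """Raised for symbols outside the amino-acid alphabet."""


class AlignmentDiscarded(Exception):
    """An alignment rejected by a preprocessing size filter.

    Attributes
    ----------
    criterion : str
        Which filter failed (``"too few sequences"``, ``"too few columns"``,
        ``"too many columns"``).
    """

    def __init__(self, criterion: str):
        self.criterion = criterion
        super().__init__(f"alignment discarded ({criterion})")


@dataclass
class Alignment:
    """A gapped protein alignment over the 20-letter alphabet.

    Parameters
    ----------
    seq_ids : list of str
        One identifier per row.
    matrix : (N, L) uint8 array
        Residue codes 0..19 (:data:`AMINO_ACIDS` order) or 20 for gap.
    col_origin : (L,) int array
        1-based original column / match-state index of each retained column;
        strictly increasing.
    """

    seq_ids: list[str]
    matrix: np.ndarray
    col_origin: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.seq_ids) != self.matrix.shape[0]:
            raise AlignmentFormatError("seq_ids length does not match matrix rows")
        if self.matrix.size and self.matrix.max() > GAP:
            raise AlphabetError("matrix contains codes outside 0..20")
        if self.col_origin is None:
            self.col_origin = np.arange(1, self.matrix.shape[1] + 1)
        self.col_origin = np.asarray(self.col_origin, dtype=int)
        if self.col_origin.shape != (self.matrix.shape[1],):
            raise AlignmentFormatError("col_origin length does not match columns")
        if self.col_origin.size > 1 and not np.all(np.diff(self.col_origin) > 0):
            raise AlignmentFormatError("col_origin must be strictly increasing")

    @property
    def n_seqs(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row_string(self, r: int) -> str:
        return "".join(
            AMINO_ACIDS[c] if c < GAP else "-" for c in self.matrix[r]
        )

    def gap_fraction_per_column(self) -> np.ndarray:
        if self.n_seqs == 0:
            return np.zeros(self.n_cols)
        return (self.matrix == GAP).mean(axis=0)

    def gap_fraction_per_sequence(self) -> np.ndarray:
        if self.n_cols == 0:
            return np.zeros(self.n_seqs)
        return (self.matrix == GAP).mean(axis=1)


@dataclass
class PreprocessConfig:
    """Filters applied before any statistics are computed.

    Defaults are plausible Pfam-scale values; the analysis does not depend on
    them and every field is configurable.
    """

    max_col_gap_frac: float = 0.5
    max_seq_gap_frac: float = 0.5
    min_seqs: int = 50
    min_cols: int = 50
    max_cols: int = 400

    def __post_init__(self):
        if not (0.0 <= self.max_col_gap_frac <= 1.0):
            raise ValueError("max_col_gap_frac must be in [0,1]")
        if not (0.0 <= self.max_seq_gap_frac <= 1.0):
            raise ValueError("max_seq_gap_frac must be in [0,1]")
        if self.min_cols > self.max_cols:
            raise ValueError("min_cols must not exceed max_cols")


def _encode_symbol(ch: str, map_ambiguous: bool = True) -> int:
    c = ch.upper()
    if c in AA_INDEX:
        return AA_INDEX[c]
    if ch in GAP_CHARS or c in GAP_CHARS:
        return GAP
    if c in AMBIGUOUS_CODES:
        if map_ambiguous:
            return GAP
        raise AlphabetError(f"ambiguous residue code {ch!r}")
    raise AlphabetError(f"unknown symbol {ch!r}")


def encode_rows(rows: Iterable[str], map_ambiguous: bool = True) -> np.ndarray:
    """Encode equal-length residue strings into the integer matrix."""
    rows = list(rows)
    if not rows:
        raise AlignmentFormatError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentFormatError("rows have unequal lengths")
    mat = np.empty((len(rows), width), dtype=np.uint8)
    for i, row in enumerate(rows):
        for j, ch in enumerate(row):
            mat[i, j] = _encode_symbol(ch, map_ambiguous)
    return mat


def _match_columns_stockholm(msa) -> np.ndarray | None:
    """Boolean mask of match columns for a Pfam-dialect Stockholm alignment.

    Prefers the ``#=GC RF`` reference annotation (non-gap characters mark
    match states); falls back to the case convention in which insert states
    are lower-case or '.'.  Returns ``None`` if neither signal is present.
    """
    rf = msa.column_annotations.get("reference_annotation")
    if rf:
        return np.array([c not in ".-~" for c in rf])
    cols = np.array([list(str(rec.seq)) for rec in msa])
    has_lower = np.vectorize(str.islower)(cols).any(axis=0)
    has_dot = (cols == ".").any(axis=0)
    insert = has_lower | has_dot
    if insert.any():
        return ~insert
    return None


def read_alignment(path: str | Path, fmt: str | None = None,
                   map_ambiguous: bool = True) -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    For FASTA the column origin is the identity.  For Stockholm, only match
    columns are retained and ``col_origin`` records their 1-based positions
    in the original alignment.
    """
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix in {".sto", ".stk", ".stockholm"} else "fasta"
    if fmt not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(str(exc)) from exc

    ids = [rec.id for rec in msa]
    rows = [str(rec.seq) for rec in msa]
    mat = encode_rows(rows, map_ambiguous=map_ambiguous)
    origin = np.arange(1, mat.shape[1] + 1)
    if fmt == "stockholm":
        mask = _match_columns_stockholm(msa)
        if mask is not None:
            mat = mat[:, mask]
            origin = origin[mask]
    return Alignment(ids, mat, origin)


def write_fasta(a: Alignment, path: str | Path) -> None:
    """Write the alignment as aligned FASTA (gaps as '-')."""
    with open(path, "w") as fh:
        for r in range(a.n_seqs):
            fh.write(f">{a.seq_ids[r]}\n{a.row_string(r)}\n")


def preprocess_alignment(a: Alignment, cfg: PreprocessConfig | None = None) -> Alignment:
    """Apply gap/duplicate/size filters; raise :class:`AlignmentDiscarded` on rejection.

    Column and sequence filters are iterated to a fixed point (dropping gappy
    sequences can change column gap fractions and vice versa), which makes the
    operation idempotent.  Duplicate sequences keep their first occurrence.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    mat = a.matrix
    ids = list(a.seq_ids)
    origin = a.col_origin

    changed = True
    while changed:
        changed = False
        if mat.shape[0]:
            col_gap = (mat == GAP).mean(axis=0)
            keep_cols = col_gap <= cfg.max_col_gap_frac
            if not keep_cols.all():
                mat = mat[:, keep_cols]
                origin = origin[keep_cols]
                changed = True
        # deduplicate rows, keeping first occurrence
        seen: dict[bytes, int] = {}
        keep_rows = np.ones(mat.shape[0], dtype=bool)
        for r in range(mat.shape[0]):
            key = mat[r].tobytes()
            if key in seen:
                keep_rows[r] = False
            else:
                seen[key] = r
        if mat.shape[1]:
            seq_gap = (mat == GAP).mean(axis=1)
            keep_rows &= seq_gap <= cfg.max_seq_gap_frac
        if not keep_rows.all():
            mat = mat[keep_rows]
            ids = [s for s, k in zip(ids, keep_rows) if k]
            changed = True

    if mat.shape[0] < cfg.min_seqs:
        raise AlignmentDiscarded("too few sequences")
    if mat.shape[1] < cfg.min_cols:
        raise AlignmentDiscarded("too few columns")
    if mat.shape[1] > cfg.max_cols:
        raise AlignmentDiscarded("too many columns")
    return Alignment(ids, mat, origin)


def column_counts(a: Alignment, i: int) -> np.ndarray:
    """Amino-acid counts ``n_a`` of column *i*; gaps are excluded."""
    if a.n_seqs == 0:
        raise ValueError("empty alignment")
    if not (0 <= i < a.n_cols):
        raise IndexError(f"column index {i} out of range for L={a.n_cols}")
    col = a.matrix[:, i]
    return np.bincount(col[col < GAP], minlength=20)[:20].astype(np.int64)


def column_summary_tsv(a: Alignment, path: str | Path) -> None:
    """Write a per-column TSV summary (index, original position, gap fraction)."""
    gapf = a.gap_fraction_per_column()
    with open(path, "w") as fh:
        fh.write("# column\torigin\tgap_fraction\n")
        for j in range(a.n_cols):
            fh.write(f"{j}\t{a.col_origin[j]}\t{gapf[j]:.6g}\n")
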