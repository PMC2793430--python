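"""Residue-residue distance and contact maps from PDB structures.

Distances are measured between representative side-chain atoms: the C-beta
atom, or C-alpha for glycine (and as a logged fallback when C-beta is
missing).  Within a multi-model (NMR) entry the per-pair distance is the
minimum over models; when several chains or structures cover the same
domain, the final distance is the median over them.  Two residues are in
*contact* when their distance is strictly below a threshold (8 Angstrom by
default, the CASP convention); primary-sequence separation is measured in
match-state positions via the alignment's column origins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMap", "ContactMap", "representative_coordinates",
    "build_distance_map", "build_contact_map", "coverage_fraction",
    "read_residue_mapping", "write_contact_tsv", "read_contact_tsv",
    "load_structure",
]

DEFAULT_CONTACT_THRESHOLD = 8.0  # Angstrom


@dataclass
class DistanceMap:
    """Symmetric L x L distances in Angstrom; NaN where no structure covers."""

    dist: np.ndarray
    source_count: np.ndarray  # per-pair number of contributing structures/chains

    def __post_init__(self):
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance map must be square")
        self.dist = d

    @property
    def n_cols(self) -> int:
        return self.dist.shape[0]


@dataclass
class ContactMap:
    """Boolean contacts below ``threshold``; NaN distance -> undefined contact.

    ``contact`` is a float matrix with values 1.0 / 0.0 / NaN (undefined) so
    that missing coverage is representable; ``sep`` holds primary-sequence
    separations in match-state units.
    """

    contact: np.ndarray
    dist: np.ndarray
    threshold: float
    sep: np.ndarray

    @property
    def n_cols(self) -> int:
        return self.contact.shape[0]

    def defined(self) -> np.ndarray:
        m = ~np.isnan(self.contact)
        np.fill_diagonal(m, False)
        return m

    def is_contact(self, i: int, j: int) -> bool:
        v = self.contact[i, j]
        if np.isnan(v):
            raise ValueError(f"contact undefined for pair ({i}, {j})")
        return bool(v)

    def contact_pairs(self) -> list[tuple[int, int]]:
        L = self.n_cols
        return [(i, j) for i in range(L) for j in range(i + 1, L)
                if self.contact[i, j] == 1.0]


def load_structure(path: str | Path, name: str | None = None):
    """Parse a PDB file (all MODEL blocks retained)."""
    parser = PDBParser(QUIET=True)
    return parser.get_structure(name or Path(path).stem, str(path))


def representative_coordinates(residue) -> np.ndarray | None:
    """C-beta coordinate of a residue; C-alpha for glycine or missing C-beta.

    Returns ``None`` when neither atom is present (e.g. incomplete models).
    """
    resname = residue.get_resname().strip().upper()
    if resname != "GLY" and "CB" in residue:
        return residue["CB"].get_coord().astype(float)
    if "CA" in residue:
        if resname != "GLY" and "CB" not in residue:
            logger.debug("residue %s %s lacks CB; falling back to CA",
                         resname, residue.get_id())
        return residue["CA"].get_coord().astype(float)
    return None


def _chain_distance_matrix(structure, chain_id: str,
                           mapping: dict[int, int], L: int) -> np.ndarray:
    """Per-entry distances: minimum over all models of the structure.

    ``mapping`` sends structure residue numbers to alignment column indices
    (0-based).
    """
    dist = np.full((L, L), np.nan)
    for model in structure:
        if chain_id not in model:
            continue
        chain = model[chain_id]
        coords: dict[int, np.ndarray] = {}
        for residue in chain:
            het, resseq, _ = residue.get_id()
            if het.strip():
                continue  # skip heteroatoms/waters
            if resseq in mapping:
                xyz = representative_coordinates(residue)
                if xyz is not None:
                    coords[mapping[resseq]] = xyz
        cols = sorted(coords)
        for a_idx, ci in enumerate(cols):
            for cj in cols[a_idx + 1:]:
                d = float(np.linalg.norm(coords[ci] - coords[cj]))
                cur = dist[ci, cj]
                if np.isnan(cur) or d < cur:  # min over models
                    dist[ci, cj] = dist[cj, ci] = d
    return dist


def build_distance_map(structures, L: int) -> DistanceMap:
    """Median-over-structures distance map.

    Parameters
    ----------
    structures : list of (structure, chain_id, mapping)
        Parsed structures with the chain to use and the residue-number ->
        column mapping (0-based columns, injective).
    L : int
        Number of alignment columns.
    """
    if not structures:
        raise ValueError("at least one structure is required")
    stack = []
    for structure, chain_id, mapping in structures:
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("residue->column mapping must be injective")
        stack.append(_chain_distance_matrix(structure, chain_id, mapping, L))
    arr = np.stack(stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(arr, axis=0)  # even count -> mean of central two
    count = (~np.isnan(arr)).sum(axis=0)
    np.fill_diagonal(med, np.nan)
    return DistanceMap(dist=med, source_count=count)


def build_contact_map(dmap: DistanceMap, threshold: float = DEFAULT_CONTACT_THRESHOLD,
                      col_origin: np.ndarray | None = None) -> ContactMap:
    """Threshold a distance map into contacts (strict ``dist < threshold``)."""
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    L = dmap.n_cols
    if col_origin is None:
        col_origin = np.arange(1, L + 1)
    col_origin = np.asarray(col_origin)
    contact = np.where(np.isnan(dmap.dist), np.nan,
                       (dmap.dist < threshold).astype(float))
    np.fill_diagonal(contact, np.nan)
    sep = np.abs(col_origin[:, None] - col_origin[None, :])
    return ContactMap(contact=contact, dist=dmap.dist.copy(),
                      threshold=threshold, sep=sep)


def coverage_fraction(dmap: DistanceMap) -> float:
    """Fraction of columns with at least one defined distance."""
    L = dmap.n_cols
    if L == 0:
        return 0.0
    covered = (~np.isnan(dmap.dist)).any(axis=1)
    return float(covered.sum() / L)


def read_residue_mapping(path: str | Path) -> dict[int, int]:
    """Two-column TSV (structure residue number, 0-based alignment column)."""
    mapping: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            res, col = line.split("\t")[:2]
            mapping[int(res)] = int(col)
    return mapping


def write_contact_tsv(cm: ContactMap, path: str | Path) -> None:
    """Serialize as ``i  j  distance  contact  separation`` for defined pairs."""
    with open(path, "w") as fh:
        fh.write(f"# threshold_angstrom={cm.threshold}\n")
        fh.write("# col_i\tcol_j\tdistance\tcontact\tseparation\n")
        L = cm.n_cols
        for i in range(L):
            for j in range(i + 1, L):
                if np.isnan(cm.contact[i, j]):
                    continue
                fh.write(f"{i}\t{j}\t{cm.dist[i, j]:.4f}\t"
                         f"{int(cm.contact[i, j])}\t{int(cm.sep[i, j])}\n")


def read_contact_tsv(path: str | Path) -> ContactMap:
    threshold = DEFAULT_CONTACT_THRESHOLD
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if "threshold_angstrom=" in line:
                    threshold = float(line.split("=")[1])
                continue
            if line:
                i, j, d, c, s = line.split("\t")
                rows.append((int(i), int(j), float(d), int(c), int(s)))
    if not rows:
        raise ValueError(f"no contact entries in {path}")
    L = max(max(i, j) for i, j, *_ in rows) + 1
    dist = np.full((L, L), np.nan)
    contact = np.full((L, L), np.nan)
    sep = np.zeros((L, L), dtype=int)
    for i, j, d, c, s in rows:
        dist[i, j] = dist[j, i] = d
        contact[i, j] = contact[j, i] = float(c)
        sep[i, j] = sep[j, i] = s
    return ContactMap(contact=contact, dist=dist, threshold=threshold, sep=sep)
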