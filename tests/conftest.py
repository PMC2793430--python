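import numpy as np
import pytest

from coevotree.msa_io import Alignment, encode_rows


@pytest.fixture
def tiny_alignment():
    """3 sequences x 5 columns, no gaps."""
    rows = ["ACDEF", "ACDEG", "ACDFG"]
    return Alignment(["s1", "s2", "s3"], encode_rows(rows))


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "aln.fa"
    p.write_text(">s1\nACDEF\n>s2\nACDEG\n>s3\nACDFG\n")
    return p


@pytest.fixture
def stockholm_file(tmp_path):
    """Stockholm with 2 insert columns (RF '.') among 5."""
    p = tmp_path / "aln.sto"
    p.write_text(
        "# STOCKHOLM 1.0\n"
        "s1 ACaDEf\n"
        "s2 ACcDGg\n"
        "s3 AC.DF.\n"
        "#=GC RF xx.xx.\n"
        "//\n"
    )
    return p


def make_pdb(residues, models=1, jitter=None):
    """Build a minimal PDB text: residues = [(resname, resseq, {atom: xyz})].

    ``jitter``: optional per-model offset added to every coordinate, one
    3-vector per model (to emulate NMR ensembles).
    """
    lines = []
    serial = 1
    for m in range(models):
        if models > 1:
            lines.append(f"MODEL     {m + 1:4d}")
        off = np.zeros(3) if jitter is None else np.asarray(jitter[m])
        for resname, resseq, atoms in residues:
            for name, xyz in atoms.items():
                x, y, z = np.asarray(xyz, dtype=float) + off
                lines.append(
                    f"ATOM  {serial:5d} {name:^4s} {resname:>3s} A{resseq:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {name[0]:>2s}"
                )
                serial += 1
        if models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pdb_factory(tmp_path):
    def _write(name, residues, models=1, jitter=None):
        p = tmp_path / name
        p.write_text(make_pdb(residues, models=models, jitter=jitter))
        return p
    return _write
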