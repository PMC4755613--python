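"""Shared fixtures: tiny alignments and a synthetic two-chain PDB file."""

import numpy as np
import pytest
from hypothesis import settings

from ppidca.alignments import LabeledMSA, encode

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def tiny_msa() -> LabeledMSA:
    """Three short rows; rows 0 and 1 identical, row 2 unrelated."""
    seqs = np.array([
        encode("ACDEF"),
        encode("ACDEF"),
        encode("WYKLM"),
    ])
    return LabeledMSA(seqs, ["ECOLI", "ECOLI", "HUMAN"],
                      ["P00001", "P00002", "P00003"])


def _pdb_atom(serial, name, resname, chain, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:>5} {name:<4}{resname:>4} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}\n"
    )


@pytest.fixture
def synthetic_pdb(tmp_path):
    """Synthetic two-chain miniature structure (not from any database).

    Chain A: three glycines along x at 0, 4 and 20 A.  Chain B: one glycine
    at (0, 5, 0) — within 8 A of A:1 and A:2 but not A:3 — plus one water
    and one hydrogen to exercise the heavy-atom and het filters.
    """
    lines = [
        _pdb_atom(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, "C"),
        _pdb_atom(2, "CA", "GLY", "A", 2, 4.0, 0.0, 0.0, "C"),
        _pdb_atom(3, "H", "GLY", "A", 2, 4.0, 0.5, 0.0, "H"),
        _pdb_atom(4, "CA", "GLY", "A", 3, 20.0, 0.0, 0.0, "C"),
        _pdb_atom(5, "CA", "GLY", "B", 1, 0.0, 5.0, 0.0, "C"),
        "HETATM    6  O   HOH B   2      0.000   5.500   0.000  1.00  0.00           O\n",
        "END\n",
    ]
    path = tmp_path / "mini_synthetic.pdb"
    path.write_text("".join(lines))
    return path
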