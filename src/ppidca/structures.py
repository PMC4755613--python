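"""Ground-truth residue contacts and interaction networks from 3D structures.

A residue pair is *in contact* when the minimum distance over all pairs of
heavy (non-hydrogen) atoms is strictly below a cutoff, 8 Å by default.
Contacts within one chain/protein are intra-protein; contacts between
chains mapped to different proteins are inter-protein, and a protein pair
counts as interacting when it has at least one inter-protein contact.
Nucleic-acid chains can be excluded (for ribonucleoprotein complexes the
RNA scaffold is not part of the protein co-evolution analysis).

Conventions chosen for bit-reproducible counts: strict inequality at the
cutoff, disordered atoms resolved to the highest-occupancy location, first
model of multi-model files, residues indexed by author-assigned numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import MMCIFParser, PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.spatial import cKDTree

_NUCLEIC_RESNAMES = {
    "A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DI",
}


@dataclass
class ContactMap:
    """Binary residue-pair contacts with per-residue chain labels.

    ``residues`` lists ``(chain_id, residue_number)`` in file order;
    ``contacts`` holds index pairs ``(i, j)`` with ``i < j`` into that list.
    """

    residues: list[tuple[str, int]]
    contacts: set[tuple[int, int]]
    cutoff: float
    atom_rule: str = "heavy"

    def __post_init__(self) -> None:
        n = len(self.residues)
        cleaned = set()
        for i, j in self.contacts:
            if i == j:
                continue
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"contact ({i}, {j}) out of range")
            cleaned.add((min(i, j), max(i, j)))
        self.contacts = cleaned

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def chain_of(self, idx: int) -> str:
        return self.residues[idx][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (*self.residues[i], *self.residues[j])
            for i, j in sorted(self.contacts)
        ]
        return pd.DataFrame(rows, columns=["chain_i", "res_i", "chain_j", "res_j"])


@dataclass
class PPITruth:
    """Interacting protein pairs: count >= 1 inter-protein contacts."""

    inter_counts: dict[tuple[str, str], int]
    interacting: set[tuple[str, str]] = field(init=False)

    def __post_init__(self) -> None:
        for pair, c in self.inter_counts.items():
            if c < 0:
                raise ValueError(f"negative contact count for {pair}")
        self.interacting = {p for p, c in self.inter_counts.items() if c >= 1}

    def is_interacting(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.interacting


def load_structure(path: str | Path):
    """Parse a PDB or mmCIF file, returning the first model."""
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        parser = MMCIFParser(QUIET=True)
    else:
        parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    return next(structure.get_models())


def _is_nucleic(residue) -> bool:
    return residue.get_resname().strip() in _NUCLEIC_RESNAMES


def _heavy_atoms(residue):
    for atom in residue.get_atoms():
        # DisorderedAtom resolves to the highest-occupancy altloc by default
        if atom.element not in ("H", "D"):
            yield atom


def contact_map(
    model,
    chains: Sequence[str] | None = None,
    cutoff: float = 8.0,
    min_separation: int = 0,
    exclude_nucleic: bool = True,
) -> ContactMap:
    """Heavy-atom residue contact map of selected chains.

    A pair is a contact iff its minimum heavy-atom distance is < ``cutoff``.
    ``min_separation`` (applied within a chain only) drops pairs closer than
    that many positions in sequence; the default 0 keeps everything, which
    is the convention for global contact totals, while evaluating
    *predicted* intra-protein contacts conventionally uses >= 5.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if chains is not None and len(chains) == 0:
        raise ValueError("empty chain selection")
    wanted = set(chains) if chains is not None else None
    residues: list[tuple[str, int]] = []
    coords: list[np.ndarray] = []
    owner: list[int] = []
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for residue in chain:
            het = residue.id[0].strip()
            if het and not is_aa(residue, standard=False):
                continue  # waters / small-molecule ligands
            if exclude_nucleic and _is_nucleic(residue):
                continue
            xyz = [a.coord for a in _heavy_atoms(residue)]
            if not xyz:
                warnings.warn(
                    f"residue {chain.id}:{residue.id[1]} has no heavy atoms; skipped",
                    stacklevel=2,
                )
                continue
            idx = len(residues)
            residues.append((chain.id, residue.id[1]))
            for c in xyz:
                coords.append(np.asarray(c, dtype=float))
                owner.append(idx)
    if not residues:
        raise ValueError("no residues selected")
    pts = np.asarray(coords)
    own = np.asarray(owner)
    tree = cKDTree(pts)
    contacts: set[tuple[int, int]] = set()
    for ai, bi in tree.query_pairs(cutoff - 1e-12):
        ri, rj = own[ai], own[bi]
        if ri == rj:
            continue
        i, j = (ri, rj) if ri < rj else (rj, ri)
        if min_separation and residues[i][0] == residues[j][0]:
            if abs(residues[i][1] - residues[j][1]) < min_separation:
                continue
        contacts.add((int(i), int(j)))
    return ContactMap(residues, contacts, cutoff)


def classify_contacts(
    cm: ContactMap, protein_of_chain: Mapping[str, str]
) -> tuple[int, int, dict[tuple[str, str], int]]:
    """Split contacts into intra- and inter-protein totals.

    ``protein_of_chain`` labels every chain with a protein identifier (so
    multi-chain proteins are possible).  Returns
    ``(intra_count, inter_count, per_pair_inter_counts)``; the two totals
    always sum to the number of contacts.
    """
    for chain, _ in cm.residues:
        if chain not in protein_of_chain:
            raise KeyError(f"chain {chain!r} has no protein label")
    intra = inter = 0
    per_pair: dict[tuple[str, str], int] = {}
    for i, j in cm.contacts:
        pa = protein_of_chain[cm.chain_of(i)]
        pb = protein_of_chain[cm.chain_of(j)]
        if pa == pb:
            intra += 1
        else:
            inter += 1
            key = tuple(sorted((pa, pb)))
            per_pair[key] = per_pair.get(key, 0) + 1
    return intra, inter, per_pair


def ppi_truth(per_pair_inter_counts: Mapping[tuple[str, str], int]) -> PPITruth:
    """Interaction ground truth: pairs with at least one inter contact."""
    return PPITruth(dict(per_pair_inter_counts))
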