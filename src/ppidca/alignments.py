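"""Labeled multiple sequence alignments: reading, integer encoding, reweighting.

Sequences are encoded over a fixed ``q = 21``-state alphabet in which the
alignment gap is treated as an additional amino-acid state.  The alphabet
order is fixed (gap first, then the 20 standard amino acids alphabetically)
so that encoded alignments, fitted coupling matrices and score matrices are
bit-reproducible across runs.  Non-standard residue codes (B, J, O, U, X, Z)
carry no information under a 21-state model and are mapped to the gap state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import AlignIO

from . import _kernels

#: Gap first, then the 20 standard amino acids in alphabetical order.
ALPHABET: str = "-ACDEFGHIKLMNPQRSTVWY"
GAP_STATE: int = 0
Q_STATES: int = len(ALPHABET)

_CHAR_TO_STATE = np.zeros(128, dtype=np.int8)  # unknown -> gap
for _i, _c in enumerate(ALPHABET):
    _CHAR_TO_STATE[ord(_c)] = _i
_CHAR_TO_STATE[ord(".")] = GAP_STATE


class MSAFormatError(ValueError):
    """Raised when an alignment file is empty, ragged, or unparseable."""


def encode(seq: str) -> np.ndarray:
    """Encode one aligned sequence into integer states.

    Uppercases the input; gaps (``-`` or ``.``) and any residue code outside
    the 20 standard amino acids map to the gap state.
    """
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_STATE[np.minimum(arr, 127)]


def decode(states: Sequence[int]) -> str:
    """Inverse of :func:`encode` for sequences over the canonical alphabet."""
    return "".join(ALPHABET[s] for s in states)


# ---------------------------------------------------------------------------
# Header schemas: how species and accession are pulled out of record headers.
# ---------------------------------------------------------------------------

def uniprot_header(header: str) -> tuple[str, str]:
    """Parse ``db|ACC|NAME_SPECIES``-style headers.

    Returns ``(accession, species)``.  Falls back to treating the whole
    identifier as the accession and the suffix after the last underscore
    (or after ``/`` coordinates are stripped) as the species.
    """
    ident = header.split()[0]
    parts = ident.split("|")
    if len(parts) >= 3:
        acc = parts[1]
        name = parts[2]
    else:
        acc = parts[0]
        name = parts[0]
    name = name.split("/")[0]
    species = name.rsplit("_", 1)[1] if "_" in name else name
    return acc, species


def plain_header(header: str) -> tuple[str, str]:
    """Use the first whitespace-delimited token as both accession and species."""
    ident = header.split()[0].split("/")[0]
    return ident, ident


HEADER_SCHEMAS: dict[str, Callable[[str], tuple[str, str]]] = {
    "uniprot": uniprot_header,
    "plain": plain_header,
}


@dataclass
class LabeledMSA:
    """An integer-encoded alignment with per-sequence species and accessions.

    Attributes
    ----------
    sequences:
        ``(M, L)`` int8 matrix of states in ``[0, q)``.
    species, accessions:
        Length-``M`` metadata lists.
    q:
        Number of states (21: 20 amino acids plus the gap).
    """

    sequences: np.ndarray
    species: list[str]
    accessions: list[str]
    q: int = Q_STATES

    def __post_init__(self) -> None:
        self.sequences = np.ascontiguousarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise ValueError("sequences must be a 2-D (M, L) matrix")
        m = self.sequences.shape[0]
        if len(self.species) != m or len(self.accessions) != m:
            raise ValueError("species/accessions must have one entry per row")
        if m and (self.sequences.min() < 0 or self.sequences.max() >= self.q):
            raise ValueError(f"states must lie in [0, {self.q})")

    @property
    def depth(self) -> int:
        """Number of rows M."""
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        """Alignment width L."""
        return self.sequences.shape[1]

    def take_rows(self, idx: Sequence[int]) -> "LabeledMSA":
        idx = list(idx)
        return LabeledMSA(
            self.sequences[idx],
            [self.species[i] for i in idx],
            [self.accessions[i] for i in idx],
            q=self.q,
        )

    def take_columns(self, start: int, stop: int) -> "LabeledMSA":
        return LabeledMSA(
            self.sequences[:, start:stop], list(self.species),
            list(self.accessions), q=self.q,
        )

    def row_str(self, i: int) -> str:
        return decode(self.sequences[i])


@dataclass
class SequenceWeights:
    """Similarity-based sequence weights.

    ``weights[m] = 1 / |{m' : identity(m, m') >= 1 - identity_threshold}|``
    (the sequence itself included), so each weight lies in ``(0, 1]`` and the
    effective sequence count ``sum(weights)`` never exceeds M.
    """

    weights: np.ndarray
    identity_threshold: float
    effective_count: float = field(init=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.effective_count = float(self.weights.sum())


def compute_weights(msa: LabeledMSA, threshold: float = 0.2) -> SequenceWeights:
    """Reweight sequences by similarity clustering.

    Two rows are neighbours when their fractional identity is at least
    ``1 - threshold``; each row's weight is the reciprocal of its neighbour
    count.  ``threshold = 0.2`` reproduces the 80 %-identity clustering used
    by plmDCA by default.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    max_mismatch = int(math.floor(threshold * msa.length + 1e-9))
    counts = _kernels.neighbor_counts(msa.sequences, max_mismatch)
    return SequenceWeights(1.0 / counts, threshold)


def read_msa(
    path: str | Path,
    format: str = "fasta",
    header_schema: str | Callable[[str], tuple[str, str]] = "uniprot",
) -> LabeledMSA:
    """Read an aligned FASTA or Stockholm file into a :class:`LabeledMSA`.

    ``header_schema`` names a registered parsing rule (``"uniprot"`` for
    ``db|ACC|NAME_SPECIES`` headers, ``"plain"``) or is a callable mapping a
    header string to ``(accession, species)``.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format: {format!r}")
    schema = HEADER_SCHEMAS[header_schema] if isinstance(header_schema, str) else header_schema
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        raise MSAFormatError(f"{path}: {exc}") from exc
    if len(aln) == 0:
        raise MSAFormatError(f"{path}: empty alignment")
    rows, species, accs = [], [], []
    width = aln.get_alignment_length()
    for rec in aln:
        s = str(rec.seq)
        if len(s) != width:
            raise MSAFormatError(f"{path}: ragged record {rec.id!r}")
        rows.append(encode(s))
        header = rec.description if rec.description else rec.id
        acc, sp = schema(header)
        accs.append(acc)
        species.append(sp)
    return LabeledMSA(np.array(rows, dtype=np.int8), species, accs)


def save_encoded(msa: LabeledMSA, path: str | Path) -> None:
    """Persist an encoded alignment to an .npz container.

    The alphabet is stored in the metadata so the integer states remain
    interpretable independently of this module's constants.
    """
    np.savez_compressed(
        path,
        sequences=msa.sequences,
        species=np.asarray(msa.species, dtype=object),
        accessions=np.asarray(msa.accessions, dtype=object),
        alphabet=np.asarray(ALPHABET),
        q=np.asarray(msa.q),
    )


def load_encoded(path: str | Path) -> LabeledMSA:
    """Inverse of :func:`save_encoded`; checks the stored alphabet."""
    with np.load(path, allow_pickle=True) as z:
        if str(z["alphabet"]) != ALPHABET:
            raise MSAFormatError(
                f"{path}: stored alphabet {z['alphabet']!r} does not match")
        return LabeledMSA(z["sequences"], list(z["species"]),
                          list(z["accessions"]), q=int(z["q"]))


def write_fasta(msa: LabeledMSA, path: str | Path) -> None:
    """Write an encoded alignment back to FASTA with composite headers."""
    with open(path, "w") as fh:
        for i in range(msa.depth):
            fh.write(f">{msa.accessions[i]}|{msa.species[i]}\n{msa.row_str(i)}\n")
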