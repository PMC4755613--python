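"""Ground-truth Potts models over artificial multi-protein complexes.

The testbed is a fictitious complex of ``N`` structurally identical proteins
arranged in a ring: protein ``i`` touches proteins ``i±1 (mod N)`` and no
others.  Every protein shares one intra-protein contact map (the template);
each interacting edge gets a random binary inter-contact map whose density
is a configured fraction (default 10 %) of the intra-contact count, so
interfaces are sparse relative to protein cores, as in real complexes.
Contacting site pairs carry coupling matrices drawn from a *pool* of
realistic coupling matrices; non-contacting pairs are exactly uncoupled.
Joint alignments are drawn from the resulting Potts model by Markov-chain
Monte Carlo, so the generating process matches the inference model's
assumptions (i.i.d. samples, no phylogeny) and end-to-end recovery of the
ring from sampled sequences is a well-posed test of the whole pipeline.

The default coupling pool is obtained by fitting the package's own
pseudo-likelihood inference to a small bundled synthetic family alignment
and keeping the strongest coupling matrices, which preserves the value
distribution and sparsity structure of inferred couplings without any
external downloads; any list of ``q x q`` matrices can be supplied instead.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from . import _kernels
from .alignments import LabeledMSA, Q_STATES, read_msa
from .matching import _ACC_ALPHABET
from .plm_inference import FitConfig, PottsModel, fit_potts
from .scoring import zero_sum_gauge

Edge = tuple[int, int]
Contact = tuple[int, int]


def banded_contact_map(length: int, max_separation: int) -> set[Contact]:
    """Template intra-contact map: all pairs within a sequence-separation band.

    A compact peptide places nearly every residue pair within a short
    separation band inside the 8 Å heavy-atom cutoff, so a band map is a
    clean deterministic stand-in for the contact map of a small template
    protein.
    """
    return {(i, j) for i in range(length) for j in range(i + 1, length)
            if 0 < j - i <= max_separation}


@dataclass
class ComplexSpec:
    """Topology of an artificial multi-protein complex.

    ``intra`` maps are per-protein local residue-index pairs; ``inter``
    maps, keyed by interaction edge ``(a, b)`` with ``a < b``, hold
    ``(i_in_a, j_in_b)`` pairs.
    """

    lengths: list[int]
    intra: list[set[Contact]]
    inter: dict[Edge, set[Contact]]
    edges: list[Edge] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.intra):
            raise ValueError("one intra map per protein required")
        self.edges = sorted(self.inter)
        for a, b in self.edges:
            if not 0 <= a < b < self.n_proteins:
                raise ValueError(f"bad edge ({a}, {b})")

    @property
    def n_proteins(self) -> int:
        return len(self.lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def offsets(self) -> list[int]:
        return [int(x) for x in np.concatenate([[0], np.cumsum(self.lengths)[:-1]])]

    def regions(self) -> list[tuple[int, int]]:
        off = self.offsets()
        return [(o, o + l) for o, l in zip(off, self.lengths)]

    def partition(self) -> list[int]:
        return [stop for _, stop in self.regions()]

    def is_edge(self, a: int, b: int) -> bool:
        return tuple(sorted((a, b))) in self.inter

    def global_contacts(self) -> set[Contact]:
        """All contacts in whole-complex column coordinates."""
        off = self.offsets()
        out: set[Contact] = set()
        for p, cmap in enumerate(self.intra):
            out |= {(off[p] + i, off[p] + j) for i, j in cmap}
        for (a, b), cmap in self.inter.items():
            for i, j in cmap:
                gi, gj = off[a] + i, off[b] + j
                out.add((min(gi, gj), max(gi, gj)))
        return out


def build_complex(
    template_contacts: set[Contact] | Sequence[Contact],
    length: int,
    n_proteins: int = 5,
    inter_density: float = 0.1,
    topology: str | Sequence[Edge] = "circular",
    seed: int = 0,
) -> ComplexSpec:
    """Replicate a template protein into a complex with random interfaces.

    Every protein reuses the template's intra map; each edge of the topology
    receives ``round(inter_density * n_intra)`` distinct inter-protein site
    pairs drawn uniformly at random.
    """
    template = {(min(i, j), max(i, j)) for i, j in template_contacts}
    if any(not 0 <= i < j < length for i, j in template):
        raise ValueError("template contacts out of range for given length")
    if not 0.0 < inter_density <= 1.0:
        raise ValueError("inter_density must be in (0, 1]")
    n_inter = round(inter_density * len(template))
    if n_inter < 1:
        raise ValueError(
            "inter-contact density rounds to zero contacts per edge; "
            "such an interface would be undetectable by construction"
        )
    if topology == "circular":
        edges = [tuple(sorted((p, (p + 1) % n_proteins)))
                 for p in range(n_proteins)]
        edges = sorted(set(edges))
    else:
        edges = sorted(tuple(sorted(e)) for e in topology)
    rng = np.random.default_rng(seed)
    inter: dict[Edge, set[Contact]] = {}
    all_pairs = [(i, j) for i in range(length) for j in range(length)]
    for edge in edges:
        picks = rng.choice(len(all_pairs), size=n_inter, replace=False)
        inter[edge] = {all_pairs[p] for p in picks}
    return ComplexSpec([length] * n_proteins, [set(template)] * n_proteins, inter)


@dataclass
class GeneratorModel:
    """A Potts model whose couplings sit exactly on a complex's contacts."""

    model: PottsModel
    spec: ComplexSpec
    seed: int
    pool_source: str = "unspecified"


def assign_couplings(
    spec: ComplexSpec,
    pool: Sequence[np.ndarray],
    seed: int = 0,
    fields: Sequence[np.ndarray] | None = None,
) -> GeneratorModel:
    """Place pool coupling matrices on the contacts of a complex.

    Each intra contact of the template gets one pool matrix (chosen with the
    given seed) replicated across all protein copies — the proteins are
    structurally identical.  Each inter contact independently receives a
    pool matrix sampled uniformly with replacement.  All other couplings are
    zero; fields default to zero unless a per-site field pool is supplied.
    """
    pool = [np.asarray(m, dtype=np.float64) for m in pool]
    if not pool:
        raise ValueError("coupling pool is empty")
    q = pool[0].shape[0]
    if any(m.shape != (q, q) for m in pool):
        raise ValueError("all pool matrices must be q x q")
    rng = np.random.default_rng(seed)
    L = spec.total_length
    J = np.zeros((L, L, q, q))
    h = np.zeros((L, q))
    off = spec.offsets()

    def put(gi: int, gj: int, mat: np.ndarray) -> None:
        J[gi, gj] = mat
        J[gj, gi] = mat.T

    template = sorted(spec.intra[0])
    intra_choice = rng.integers(0, len(pool), size=len(template))
    for (i, j), c in zip(template, intra_choice):
        for p in range(spec.n_proteins):
            put(off[p] + i, off[p] + j, pool[c])
    for edge in spec.edges:
        a, b = edge
        for i, j in sorted(spec.inter[edge]):
            put(off[a] + i, off[b] + j, pool[rng.integers(0, len(pool))])
    if fields is not None:
        fields = [np.asarray(f, dtype=np.float64) for f in fields]
        idx = rng.integers(0, len(fields), size=L)
        for i in range(L):
            h[i] = fields[idx[i]]
    model = PottsModel(h, J, spec.partition())
    return GeneratorModel(model, spec, seed)


def _neighbor_arrays(model: PottsModel):
    """Dense neighbour structure of the nonzero coupling blocks."""
    L, q = model.length, model.q
    nbrs_of: list[list[int]] = [[] for _ in range(L)]
    for i in range(L):
        for j in range(L):
            if i != j and np.any(model.J[i, j]):
                nbrs_of[i].append(j)
    maxdeg = max((len(n) for n in nbrs_of), default=0)
    maxdeg = max(maxdeg, 1)
    nbrs = np.zeros((L, maxdeg), dtype=np.int64)
    deg = np.zeros(L, dtype=np.int64)
    Jn = np.zeros((L, maxdeg, q, q))
    for i, lst in enumerate(nbrs_of):
        deg[i] = len(lst)
        for d, j in enumerate(lst):
            nbrs[i, d] = j
            # Jn[i, d, state_j, state_i]: contiguous in the updated site
            Jn[i, d] = model.J[i, j].T
    return nbrs, deg, Jn


def sample_msa(
    model: GeneratorModel | PottsModel,
    n_samples: int,
    sweeps_between_samples: int = 10,
    burn_in: int = 1000,
    seed: int = 0,
    species_prefix: str = "SP",
) -> LabeledMSA:
    """Draw a joint alignment from a Potts model by Gibbs sampling.

    Single-site Gibbs updates in sequential sweep order target the model's
    Boltzmann distribution exactly; ``n_samples`` states are recorded every
    ``sweeps_between_samples`` sweeps after ``burn_in`` sweeps.  Each sample
    is labeled as its own species so that downstream matching is the
    identity (paralog-rich variants are built with :func:`paralogize`).
    """
    potts = model.model if isinstance(model, GeneratorModel) else model
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if sweeps_between_samples < 1 or burn_in < 1:
        raise ValueError("sweeps and burn-in must be >= 1")
    nbrs, deg, Jn = _neighbor_arrays(potts)
    X = _kernels.gibbs_sample(
        potts.h, Jn, nbrs, deg, int(n_samples), int(burn_in),
        int(sweeps_between_samples), int(seed) % (2**31),
    )
    species = [f"{species_prefix}{i:06d}" for i in range(n_samples)]
    accessions = [accession_from_ordinal((i + 1) * 64) for i in range(n_samples)]
    return LabeledMSA(X, species, accessions, q=potts.q)


def accession_from_ordinal(value: int, width: int = 6) -> str:
    """Inverse of the accession ordinal encoding (uniform base-36)."""
    digits = []
    for _ in range(width):
        value, r = divmod(value, len(_ACC_ALPHABET))
        digits.append(_ACC_ALPHABET[r])
    return "".join(reversed(digits))


def split_families(
    joint: LabeledMSA, spec: ComplexSpec, accession_stride: int = 1
) -> list[LabeledMSA]:
    """Cut a joint alignment into per-protein family alignments.

    Row ``m`` of protein ``p`` receives an accession ``p * stride`` ordinal
    positions after the row's base accession, emulating co-operonic genes
    deposited under adjacent accession numbers, so genomic-proximity
    matching can reassemble the original pairing.
    """
    from .matching import accession_ordinal

    fams = []
    for p, (start, stop) in enumerate(spec.regions()):
        fam = joint.take_columns(start, stop)
        fam.accessions = [
            accession_from_ordinal(accession_ordinal(acc) + p * accession_stride)
            for acc in joint.accessions
        ]
        fams.append(fam)
    return fams


def paralogize(
    families: Sequence[LabeledMSA],
    paralog_fraction: float = 0.5,
    seed: int = 0,
) -> list[LabeledMSA]:
    """Merge consecutive species pairwise to create paralog-rich families.

    A ``paralog_fraction`` of species keep two sequence pairs each (two
    genuine partner pairs sharing one species label, with accession clusters
    separated by a large gap so proximity matching can resolve them); the
    rest stay singletons.  Used to compare matching strategies: unique-only
    matching loses the merged species entirely, randomized matching scrambles
    them.
    """
    rng = np.random.default_rng(seed)
    m = families[0].depth
    merged_species: list[str] = []
    i = 0
    labels = [None] * m
    while i < m:
        if i + 1 < m and rng.random() < paralog_fraction:
            lab = f"MS{len(merged_species):06d}"
            labels[i] = labels[i + 1] = lab
            i += 2
        else:
            lab = f"MS{len(merged_species):06d}"
            labels[i] = lab
            i += 1
        merged_species.append(lab)
    out = []
    for fam in families:
        clone = LabeledMSA(fam.sequences.copy(), list(labels),
                           list(fam.accessions), q=fam.q)
        out.append(clone)
    return out


_POOL_RESOURCE = "pool_family_synthetic.fasta"


@functools.lru_cache(maxsize=1)
def default_coupling_pool(n_top: int = 8) -> tuple[np.ndarray, ...]:
    """Coupling pool from the bundled synthetic family alignment.

    Fits the packaged alignment by pseudo-likelihood and returns the
    ``n_top`` coupling matrices with the largest zero-sum-gauge Frobenius
    norms.  Cached; deterministic.
    """
    with resources.as_file(
        resources.files("ppidca").joinpath("data", _POOL_RESOURCE)
    ) as path:
        msa = read_msa(path, "fasta", "plain")
    model = fit_potts(msa, FitConfig())
    return tuple(coupling_pool_from_model(model, n_top))


def coupling_pool_from_model(model: PottsModel, n_top: int = 8) -> list[np.ndarray]:
    """The ``n_top`` strongest coupling matrices of a fitted model."""
    L = model.length
    norms = []
    for i in range(L):
        for j in range(i + 1, L):
            norms.append((float(np.linalg.norm(zero_sum_gauge(model.J[i, j]))), i, j))
    norms.sort(reverse=True)
    return [model.J[i, j].copy() for _, i, j in norms[:n_top]]


def scaled_demo_complex(
    length: int = 10,
    n_proteins: int = 5,
    inter_density: float = 0.1,
    max_separation: int = 6,
    seed: int = 0,
) -> ComplexSpec:
    """The desk-scale ring complex used throughout the test experiments.

    Five proteins of length 10 with a separation-band intra map (39
    contacts) and 10 %-density interfaces (4 inter contacts per edge).
    """
    template = banded_contact_map(length, max_separation)
    return build_complex(template, length, n_proteins, inter_density,
                         "circular", seed)
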