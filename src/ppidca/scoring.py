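"""From fitted couplings to residue co-evolution and interaction scores.

The residue-level score of a site pair is the Frobenius norm of its coupling
matrix taken in the zero-sum gauge (every row and column of the matrix
averaging to zero).  The gauge matters: Potts parameters are only defined up
to per-site shifts that can be absorbed into the fields, and the zero-sum
gauge is the one in which the norm measures genuine pairwise co-variation.
The average-product correction (APC) then removes background signal shared
across a whole row or column of the score matrix — typically phylogenetic or
conservation bias.  A protein pair's interaction score is the mean of the
``k`` (default 4) largest corrected scores over its inter-protein site
pairs; averaging a handful of top scores targets the strongest interface
signal while damping single-pair noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignments import GAP_STATE
from .plm_inference import PottsModel


def zero_sum_gauge(J_ij: np.ndarray) -> np.ndarray:
    """Shift a coupling matrix so every row and column mean is zero.

    ``J'(a, b) = J(a, b) - mean_a J(., b) - mean_b J(a, .) + mean J``.
    Adding a constant to a whole row or column of ``J`` (a gauge shift that
    fields can absorb) leaves the result unchanged.
    """
    J = np.asarray(J_ij, dtype=np.float64)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("coupling matrix must be square")
    return J - J.mean(axis=0, keepdims=True) - J.mean(axis=1, keepdims=True) + J.mean()


@dataclass
class ScoreMatrix:
    """Symmetric residue–residue co-evolution scores with protein regions.

    ``raw`` holds the gauge-fixed Frobenius norms, ``apc`` the
    average-product corrected values; the diagonal is zero by convention and
    ignored throughout.
    """

    raw: np.ndarray
    apc: np.ndarray
    partition: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=np.float64)
        self.apc = np.asarray(self.apc, dtype=np.float64)
        if self.raw.shape != self.apc.shape or self.raw.ndim != 2:
            raise ValueError("raw and apc must be equal-shape square matrices")
        if not self.partition:
            self.partition = [self.raw.shape[0]]

    @property
    def length(self) -> int:
        return self.raw.shape[0]

    def regions(self) -> list[tuple[int, int]]:
        starts = [0] + list(self.partition[:-1])
        return list(zip(starts, self.partition))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the upper triangle (i < j)."""
        iu = np.triu_indices(self.length, 1)
        region_of = np.zeros(self.length, dtype=int)
        for ridx, (start, stop) in enumerate(self.regions()):
            region_of[start:stop] = ridx
        return pd.DataFrame({
            "i": iu[0], "j": iu[1],
            "region_i": region_of[iu[0]], "region_j": region_of[iu[1]],
            "F": self.raw[iu], "F_apc": self.apc[iu],
        })


def apc_matrix(F: np.ndarray) -> np.ndarray:
    """Average-product correction with off-diagonal arithmetic means.

    ``F_apc(i,j) = F(i,j) - mean_i(F) * mean_j(F) / mean(F)`` where all
    means run over off-diagonal entries.  An all-zero input returns all
    zeros (no division by zero); a constant off-diagonal matrix is
    annihilated exactly.
    """
    F = np.asarray(F, dtype=np.float64)
    L = F.shape[0]
    if L < 2:
        return np.zeros_like(F)
    off = ~np.eye(L, dtype=bool)
    total = F[off].mean()
    if total == 0.0:
        return np.zeros_like(F)
    row = (F.sum(axis=1) - np.diag(F)) / (L - 1)
    out = F - np.outer(row, row) / total
    np.fill_diagonal(out, 0.0)
    return out


def frobenius_scores(
    model: PottsModel, exclude_gap: bool | None = None
) -> ScoreMatrix:
    """Gauge-fixed Frobenius norms of all coupling matrices, plus APC.

    For the canonical 21-state alphabet the gap row/column carries alignment
    artefacts rather than co-evolution and is excluded from the norm (the
    20 x 20 amino-acid block is gauge-fixed and measured); pass
    ``exclude_gap=False`` to include it.  Models over other state counts
    include all states by default.
    """
    if exclude_gap is None:
        exclude_gap = model.q == 21
    L = model.length
    raw = np.zeros((L, L))
    keep = np.arange(model.q)
    if exclude_gap:
        keep = keep[keep != GAP_STATE]
    for i in range(L):
        for j in range(i + 1, L):
            block = model.J[i, j][np.ix_(keep, keep)]
            raw[i, j] = raw[j, i] = float(
                np.linalg.norm(zero_sum_gauge(block)))
    return ScoreMatrix(raw, apc_matrix(raw), list(model.partition))


def apc_correct(scores: ScoreMatrix) -> ScoreMatrix:
    """Return a copy of ``scores`` with the APC recomputed from ``raw``."""
    return ScoreMatrix(scores.raw.copy(), apc_matrix(scores.raw),
                       list(scores.partition))


def interaction_score(
    scores: ScoreMatrix,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    k: int = 4,
    use_apc: bool = True,
) -> float:
    """Mean of the ``k`` largest inter-region residue scores.

    If fewer than ``k`` inter-region site pairs exist, all of them are
    averaged.  Regions must be disjoint column intervals.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    (a0, a1), (b0, b1) = region_a, region_b
    if max(a0, b0) < min(a1, b1):
        raise ValueError(f"regions {region_a} and {region_b} overlap")
    mat = scores.apc if use_apc else scores.raw
    block = mat[a0:a1, b0:b1].ravel()
    if block.size == 0:
        raise ValueError("empty inter-region block")
    top = np.sort(block)[-min(k, block.size):]
    return float(top.mean())


@dataclass
class PairScoreTable:
    """Per-protein-pair interaction scores, one row per unordered pair."""

    frame: pd.DataFrame

    COLUMNS = ("protein_a", "protein_b", "score", "k", "n_inter_pairs", "depth")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        key = self.frame[["protein_a", "protein_b"]].apply(
            lambda r: tuple(sorted((r.iloc[0], r.iloc[1]))), axis=1)
        if key.duplicated().any():
            raise ValueError("one row per unordered protein pair required")


def rank_predictions(table: PairScoreTable) -> pd.DataFrame:
    """Order pairs by descending score; ties break lexicographically.

    Pairs with a null score (for example, empty matched alignments) are
    excluded from the ranking.
    """
    df = table.frame
    if len(df) == 0:
        raise ValueError("empty score table")
    df = df[df["score"].notna()].copy()
    df = df.sort_values(
        by=["score", "protein_a", "protein_b"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def make_pair_table(rows: Sequence[dict]) -> PairScoreTable:
    """Assemble a :class:`PairScoreTable` from per-pair result dicts."""
    return PairScoreTable(pd.DataFrame(list(rows), columns=list(PairScoreTable.COLUMNS)))
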