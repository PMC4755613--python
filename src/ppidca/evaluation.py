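"""Network-level experiments: paired and combined strategies, TP curves, ROC.

The *paired* strategy fits one Potts model per protein pair on the
concatenated two-family alignment and is the generally applicable route
(total length stays small).  The *combined* strategy fits a single model
over the full multi-protein concatenation, modelling all interactions
simultaneously; it is only feasible for short complexes but disentangles
indirect correlations (protein 1 and 3 of a ring correlate through the
paths 1–2–3 and 1–5–4–3, which the paired strategy must absorb into direct
1–3 couplings, inflating non-edge scores).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .alignments import LabeledMSA
from .matching import match_and_concatenate
from .plm_inference import FitConfig, fit_paired, fit_potts
from .scoring import (
    PairScoreTable,
    ScoreMatrix,
    frobenius_scores,
    interaction_score,
    make_pair_table,
    rank_predictions,
)

logger = logging.getLogger(__name__)


@dataclass
class NetworkPrediction:
    """Ranked protein-pair predictions plus the residue-level evidence."""

    table: PairScoreTable
    residue_scores: dict[tuple[str, str], ScoreMatrix]
    strategy: str = "paired"

    def ranking(self) -> pd.DataFrame:
        return rank_predictions(self.table)


def infer_network_paired(
    msas: Mapping[str, LabeledMSA],
    threshold: float = float("inf"),
    match_strategy: str = "genomic_proximity",
    fit_config: FitConfig | None = None,
    k: int = 4,
    seed: int = 0,
) -> NetworkPrediction:
    """Score every unordered family pair with its own two-protein model.

    For each pair: match-and-concatenate the two family alignments, fit by
    pseudo-likelihood, compute APC-corrected Frobenius scores and take the
    top-``k`` inter-region mean.  Pairs whose matched alignment is empty (or
    a single row) are reported with a null score and excluded from ranking.
    """
    names = list(msas)
    if len(names) < 2:
        raise ValueError("need at least 2 families")
    rows = []
    residue_scores: dict[tuple[str, str], ScoreMatrix] = {}
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            na, nb = names[ai], names[bi]
            paired = match_and_concatenate(
                msas[na], msas[nb], threshold, match_strategy, seed)
            if paired.msa.depth < 2:
                logger.warning("pair (%s, %s): matched alignment too small "
                               "(M=%d); null score", na, nb, paired.msa.depth)
                rows.append(dict(protein_a=na, protein_b=nb, score=np.nan,
                                 k=k, n_inter_pairs=0, depth=paired.msa.depth))
                continue
            model = fit_paired(paired, fit_config)
            scores = frobenius_scores(model)
            ra, rb = scores.regions()
            s = interaction_score(scores, ra, rb, k=k)
            residue_scores[(na, nb)] = scores
            rows.append(dict(
                protein_a=na, protein_b=nb, score=s, k=k,
                n_inter_pairs=(ra[1] - ra[0]) * (rb[1] - rb[0]),
                depth=paired.msa.depth,
            ))
    return NetworkPrediction(make_pair_table(rows), residue_scores, "paired")


def infer_network_combined(
    joint: LabeledMSA,
    partition: Sequence[int],
    names: Sequence[str] | None = None,
    fit_config: FitConfig | None = None,
    k: int = 4,
) -> NetworkPrediction:
    """One model over the full concatenation; score every region pair."""
    partition = list(partition)
    if len(partition) < 2:
        raise ValueError("partition must define at least 2 regions")
    model = fit_potts(joint, fit_config, partition=partition)
    scores = frobenius_scores(model)
    regions = scores.regions()
    if names is None:
        names = [f"P{i + 1}" for i in range(len(regions))]
    rows = []
    residue_scores: dict[tuple[str, str], ScoreMatrix] = {}
    for ai in range(len(regions)):
        for bi in range(ai + 1, len(regions)):
            ra, rb = regions[ai], regions[bi]
            s = interaction_score(scores, ra, rb, k=k)
            residue_scores[(names[ai], names[bi])] = scores
            rows.append(dict(
                protein_a=names[ai], protein_b=names[bi], score=s, k=k,
                n_inter_pairs=(ra[1] - ra[0]) * (rb[1] - rb[0]),
                depth=joint.depth,
            ))
    return NetworkPrediction(make_pair_table(rows), residue_scores, "combined")


@dataclass
class TPCurve:
    """Fraction of true positives among the first n predictions, for each n."""

    n: np.ndarray
    tp_fraction: np.ndarray
    best_possible: np.ndarray
    random_expectation: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": self.n, "tp_fraction": self.tp_fraction,
            "best_possible": self.best_possible,
            "random_expectation": self.random_expectation,
        })


def tp_curve(
    ranked_pairs: Sequence[tuple[str, str]],
    truth_positive: set[tuple[str, str]],
) -> TPCurve:
    """True-positive fraction of the top-n ranked pairs, with baselines.

    The best-possible baseline is the curve of a ranking that places all
    positives first; the random baseline is the constant positives/pairs.
    """
    keys = [tuple(sorted(p)) for p in ranked_pairs]
    pos = {tuple(sorted(p)) for p in truth_positive}
    hits = np.array([k in pos for k in keys], dtype=float)
    n = np.arange(1, len(keys) + 1)
    frac = np.cumsum(hits) / n
    n_pos = len(pos & set(keys))
    best = np.minimum(n, n_pos) / n
    rand = np.full(len(keys), n_pos / len(keys) if keys else 0.0)
    return TPCurve(n, frac, best, rand)


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[pd.DataFrame, float]:
    """ROC curve and area under it.

    The AUC equals the probability that a uniformly chosen positive
    outscores a uniformly chosen negative, with ties counted half — 1/2 for
    random scores, 1 for perfect separation.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def residue_tp_rate(
    scores: ScoreMatrix,
    contacts: set[tuple[int, int]],
    n: int,
    scope: str = "inter",
    min_separation: int = 0,
    region: tuple[int, int] | None = None,
) -> float:
    """Fraction of the top-n scored residue pairs (within scope) in contact.

    ``scope="intra"`` restricts candidates to pairs inside one region
    (optionally a single ``region``) with sequence separation at least
    ``min_separation`` — the same filter applies to candidates and truth.
    ``scope="inter"`` takes pairs spanning two different regions.
    """
    if scope not in ("intra", "inter"):
        raise ValueError("scope must be 'intra' or 'inter'")
    L = scores.length
    region_of = np.zeros(L, dtype=int)
    for ridx, (start, stop) in enumerate(scores.regions()):
        region_of[start:stop] = ridx
    contacts = {(min(i, j), max(i, j)) for i, j in contacts}
    cand = []
    for i in range(L):
        for j in range(i + 1, L):
            same = region_of[i] == region_of[j]
            if scope == "intra":
                if not same or (j - i) < min_separation:
                    continue
                if region is not None and not (region[0] <= i < region[1]):
                    continue
            else:
                if same:
                    continue
            cand.append((scores.apc[i, j], i, j))
    if not cand:
        raise ValueError("no candidate pairs in scope")
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    top = cand[:n]
    return float(np.mean([(i, j) in contacts for _, i, j in top]))
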