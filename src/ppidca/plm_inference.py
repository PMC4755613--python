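"""Potts model inference by regularized, reweighted pseudo-likelihood.

The sequence model is a pairwise Markov random field over aligned sequences
``x = (x_1 .. x_L)`` with ``q`` states per site:

    P(x) = exp( sum_{i<j} J_ij(x_i, x_j) + sum_i h_i(x_i) ) / Z .

The normalizer ``Z`` is never evaluated: parameters are obtained by
maximizing the *pseudo-likelihood* — the product over sites of the exact
conditional probability of each site's state given the rest — which needs
only per-site softmax normalizations.  The default fitting route is the
asymmetric variant (independent per-site multinomial regressions followed by
symmetrization), as in the plmDCA lineage; a symmetric variant sharing one
coupling matrix per pair is available for small problems and oracles.

The fitting objective is the weighted *mean* negative pseudo-log-likelihood
plus ``lambda_h ||h||^2 + lambda_J ||J||^2`` with both strengths 0.01 on that
per-effective-sequence scale, the convention under which the usual plmDCA
defaults are stated.  :func:`pseudo_loglikelihood` itself reports the
weighted *sum* form (so that, e.g., doubling every weight doubles the
unpenalized objective), with its own optional absolute penalties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from . import _kernels
from .alignments import LabeledMSA, SequenceWeights, compute_weights

#: Hard limit on alignment width: pseudo-likelihood maximization has
#: O(L^2 q^2) parameters and becomes impractical beyond total length ~1000.
MAX_LENGTH = 1000


@dataclass
class FitConfig:
    """Hyper-parameters of the pseudo-likelihood fit.

    ``lambda_h``/``lambda_J`` are L2 strengths on the mean-objective scale
    (plmDCA convention); ``identity_threshold`` controls sequence
    reweighting; ``tol`` is the projected-gradient infinity-norm stopping
    rule of the quasi-Newton optimizer.
    """

    lambda_h: float = 0.01
    lambda_J: float = 0.01
    identity_threshold: float = 0.2
    tol: float = 1e-3
    max_iter: int = 100
    seed: int = 0
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.lambda_h < 0 or self.lambda_J < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.tol <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class PottsModel:
    """Fields ``h[i, a]`` and couplings ``J[i, j, a, b]`` of a Potts model.

    ``J`` is stored as a full ``(L, L, q, q)`` array obeying
    ``J[i, j, a, b] == J[j, i, b, a]`` with zero diagonal blocks.
    ``partition`` lists the protein-region end columns (strictly increasing,
    ending at L) for paired or combined alignments.
    """

    h: np.ndarray
    J: np.ndarray
    partition: list[int] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.J = np.asarray(self.J, dtype=np.float64)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError("J must have shape (L, L, q, q)")
        if not self.partition:
            self.partition = [L]
        if list(self.partition) != sorted(set(self.partition)) or self.partition[-1] != L:
            raise ValueError("partition must be strictly increasing and end at L")

    @property
    def length(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def coupling(self, i: int, j: int) -> np.ndarray:
        """The q x q matrix ``J_ij`` (state at i indexes rows)."""
        return self.J[i, j]

    def regions(self) -> list[tuple[int, int]]:
        """Protein regions as (start, stop) column intervals."""
        starts = [0] + list(self.partition[:-1])
        return list(zip(starts, self.partition))

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, h=self.h, J=self.J,
            partition=np.asarray(self.partition, dtype=np.int64),
            converged=np.asarray(self.converged),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PottsModel":
        with np.load(path) as z:
            return cls(z["h"], z["J"], list(z["partition"]),
                       bool(z["converged"]))


def _symmetrize(Jc: np.ndarray) -> np.ndarray:
    """Average the two per-site estimates of each coupling matrix.

    ``Jc[r, j, b, a]`` is site ``r``'s estimate of the logit contribution of
    state ``b`` at ``j`` to state ``a`` at ``r``; in model orientation that
    is ``J_rj(a, b) = Jc[r, j, b, a]``.
    """
    J_model = np.transpose(Jc, (0, 1, 3, 2))         # J_model[i,j,a,b]
    J_other = np.transpose(Jc, (1, 0, 2, 3))         # site-j estimate of same
    J = 0.5 * (J_model + J_other)
    L = J.shape[0]
    J[np.arange(L), np.arange(L)] = 0.0
    return J


def pseudo_loglikelihood(
    model: PottsModel,
    msa: LabeledMSA,
    weights: SequenceWeights,
    lambda_h: float = 0.0,
    lambda_J: float = 0.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted-sum pseudo-log-likelihood of a symmetric model, with gradient.

    Returns ``(value, grad_h, grad_J)`` where the value is

        sum_m w_m sum_r log P(x_mr | x_m,-r)  -  lambda_h ||h||^2
                                              -  lambda_J sum_{i<j} ||J_ij||^2

    and the gradients (wrt ``h`` and the upper-triangular couplings, mirrored
    symmetrically into the full ``J`` array) are exact.  At zero parameters
    the value is ``effective_count * L * log(1/q)``.
    """
    if model.length != msa.length or model.q != msa.q:
        raise ValueError("model and alignment dimensions do not match")
    X = msa.sequences.astype(np.int64)
    m_rows, L = X.shape
    q = model.q
    w = weights.weights
    # logits[m, r, a] = h[r, a] + sum_{j != r} J[r, j, a, x_mj]
    logits = np.broadcast_to(model.h, (m_rows, L, q)).copy()
    for j in range(L):
        # contribution of observed state at j to every other site's logits
        contrib = model.J[:, j, :, :]                    # (L, q, q)
        logits += np.transpose(contrib[:, :, X[:, j]], (2, 0, 1))
        logits[:, j, :] -= contrib[j, :, X[:, j]]        # remove the j==r term
    mx = logits.max(axis=2, keepdims=True)
    ex = np.exp(logits - mx)
    Zs = ex.sum(axis=2)
    logp = (np.take_along_axis(logits, X[:, :, None], axis=2)[:, :, 0]
            - mx[:, :, 0] - np.log(Zs))
    value = float(np.sum(w[:, None] * logp))
    # gradient: for each site r, (onehot - softmax) weighted
    P = ex / Zs[:, :, None]
    G = -P * w[:, None, None]
    np.add.at(G, (np.arange(m_rows)[:, None], np.arange(L)[None, :], X), w[:, None])
    grad_h = G.sum(axis=0)
    onehot = np.zeros((m_rows, L, q))
    onehot[np.arange(m_rows)[:, None], np.arange(L)[None, :], X] = 1.0
    # dvalue/dJ[i,j,a,b] for i<j: sum_m w_m [ (1(x_i=a)-P_i(a)) 1(x_j=b)
    #                                        + 1(x_i=a)(1(x_j=b)-P_j(b)) ]
    grad_J = np.zeros_like(model.J)
    for i in range(L):
        for j in range(i + 1, L):
            gij = G[:, i, :].T @ onehot[:, j, :] + onehot[:, i, :].T @ G[:, j, :]
            grad_J[i, j] = gij
            grad_J[j, i] = gij.T
    if lambda_h:
        value -= lambda_h * float(np.sum(model.h ** 2))
        grad_h -= 2.0 * lambda_h * model.h
    if lambda_J:
        iu = np.triu_indices(L, 1)
        value -= lambda_J * float(np.sum(model.J[iu] ** 2))
        grad_J -= 2.0 * lambda_J * model.J
        grad_J[np.arange(L), np.arange(L)] = 0.0
    return value, grad_h, grad_J


def _initial_fields(X: np.ndarray, w: np.ndarray, q: int) -> np.ndarray:
    """Smoothed log column frequencies — a deterministic warm start."""
    L = X.shape[1]
    h0 = np.empty((L, q))
    for r in range(L):
        freq = np.bincount(X[:, r], weights=w, minlength=q) + 1.0 / q
        freq /= freq.sum()
        h0[r] = np.log(freq)
        h0[r] -= h0[r].mean()
    return h0


def fit_potts(
    msa: LabeledMSA,
    config: FitConfig | None = None,
    weights: SequenceWeights | None = None,
    partition: Sequence[int] | None = None,
) -> PottsModel:
    """Fit a Potts model to an alignment by pseudo-likelihood maximization.

    Sequence weights are computed on the alignment actually fitted (important
    for paired alignments, where matching can introduce duplicates) unless
    given explicitly.  Deterministic: the optimizer starts from smoothed log
    column frequencies for the fields and zero couplings, and the penalized
    objective is strictly concave.
    """
    config = config or FitConfig()
    if msa.depth < 2:
        raise ValueError("need at least 2 sequences")
    if msa.length < 2:
        raise ValueError("need at least 2 columns")
    if msa.length > MAX_LENGTH:
        raise ValueError(
            f"alignment width {msa.length} exceeds the practical limit "
            f"L <= {MAX_LENGTH} for pseudo-likelihood maximization"
        )
    if weights is None:
        weights = compute_weights(msa, config.identity_threshold)
    wbar = weights.weights / weights.effective_count
    X = np.ascontiguousarray(msa.sequences, dtype=np.int8)
    L, q = msa.length, msa.q

    if config.symmetric:
        model = _fit_symmetric(msa, weights, config)
    else:
        h0 = _initial_fields(X.astype(np.int64), wbar, q)
        x0 = np.concatenate([h0.ravel(), np.zeros(L * L * q * q)])
        nh = L * q

        def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
            h = x[:nh].reshape(L, q)
            Jc = x[nh:].reshape(L, L, q, q)
            f, gh, gJ = _kernels.plm_value_grad(
                X, wbar, h, Jc, config.lambda_h, config.lambda_J
            )
            return f, np.concatenate([gh.ravel(), gJ.ravel()])

        res = minimize(
            fun, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": config.max_iter, "gtol": config.tol,
                     "ftol": 1e-9, "maxcor": 8},
        )
        Jc = res.x[nh:].reshape(L, L, q, q)
        model = PottsModel(res.x[:nh].reshape(L, q), _symmetrize(Jc))
        model.converged = bool(res.success or res.status == 0)
        if not model.converged:
            warnings.warn(
                f"pseudo-likelihood fit stopped early: {res.message}",
                RuntimeWarning, stacklevel=2,
            )
    if partition is not None:
        model.partition = list(partition)
        if model.partition[-1] != L:
            raise ValueError("partition must end at L")
    return model


def _fit_symmetric(msa, weights, config) -> PottsModel:
    """Symmetric-parameterization fit; quadratic cost, for small problems."""
    L, q = msa.length, msa.q
    meff = weights.effective_count
    iu = np.triu_indices(L, 1)
    npair = len(iu[0])

    def unpack(x):
        h = x[: L * q].reshape(L, q)
        Jt = x[L * q:].reshape(npair, q, q)
        J = np.zeros((L, L, q, q))
        J[iu] = Jt
        J[iu[1], iu[0]] = np.transpose(Jt, (0, 2, 1))
        return h, J

    def fun(x):
        h, J = unpack(x)
        model = PottsModel(h, J)
        val, gh, gJ = pseudo_loglikelihood(model, msa, weights)
        # convert to mean-form penalized minimization
        f = -val / meff + config.lambda_h * np.sum(h ** 2) \
            + config.lambda_J * np.sum(J[iu] ** 2)
        gh = -gh / meff + 2 * config.lambda_h * h
        gJt = -gJ[iu] / meff + 2 * config.lambda_J * J[iu]
        return f, np.concatenate([gh.ravel(), gJt.ravel()])

    x0 = np.zeros(L * q + npair * q * q)
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": max(config.max_iter, 500),
                            "gtol": config.tol, "ftol": 1e-12})
    h, J = unpack(res.x)
    model = PottsModel(h, J)
    model.converged = bool(res.success or res.status == 0)
    return model


def fit_paired(paired, config: FitConfig | None = None) -> PottsModel:
    """Fit a two-protein Potts model on a paired alignment.

    Identical to :func:`fit_potts` on the concatenated matrix, with the
    protein boundary recorded as ``partition = [L_A, L_A + L_B]``.
    """
    msa = paired.msa
    return fit_potts(msa, config, partition=[paired.boundary, msa.length])
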