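"""Numba kernels: sequence reweighting, pseudo-likelihood, Gibbs sampling.

These are the only hot loops in the package.  Layout conventions:

* alignments are ``(M, L)`` int8 matrices of states in ``[0, q)``;
* the asymmetric pseudo-likelihood parameterizes, for each site ``r``, a
  conditional multinomial with logits
  ``h[r, a] + sum_{j != r} Jc[r, j, x_j, a]`` — note the *last* axis of
  ``Jc`` is the state of the site being predicted, so the innermost loop
  runs over contiguous memory;
* the Gibbs sampler receives couplings as ``Jn[i, d, b, a]``: the logit
  contribution to state ``a`` at site ``i`` from neighbour ``d`` in state
  ``b``; the sampler touches only declared neighbours, which is what makes
  sparse generator models cheap to sample.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def neighbor_counts(X, max_mismatch):
    """Count, per row, how many rows are within ``max_mismatch`` mismatches.

    Each row counts itself.  Early exit after ``max_mismatch + 1`` mismatches
    keeps this near O(M^2) with a small constant for diverged alignments.
    """
    m, length = X.shape
    counts = np.ones(m, dtype=np.float64)
    for i in range(m):
        for k in range(i + 1, m):
            mism = 0
            for l in range(length):
                if X[i, l] != X[k, l]:
                    mism += 1
                    if mism > max_mismatch:
                        break
            if mism <= max_mismatch:
                counts[i] += 1.0
                counts[k] += 1.0
    return counts


@njit(cache=True, fastmath=True)
def plm_value_grad(X, w, h, Jc, lam_h, lam_j):
    """Negative mean pseudo-log-likelihood and its gradient.

    Parameters
    ----------
    X : (M, L) int8 alignment.
    w : (M,) float64 weights, expected to sum to 1.
    h : (L, q) float64 fields.
    Jc : (L, L, q, q) float64 site-conditional couplings ``Jc[r, j, b, a]``
        (diagonal blocks ignored; their gradient is returned as the pure
        penalty term so a zero initialization stays exactly zero).
    lam_h, lam_j : L2 penalty strengths on the mean-objective scale.

    Returns
    -------
    f : float — value of the penalized negative objective (to minimize).
    gh, gJ : gradients of ``f`` with the shapes of ``h`` and ``Jc``.
    """
    m_rows, length = X.shape
    q = h.shape[1]
    gh = np.zeros_like(h)
    gJ = np.zeros_like(Jc)
    logits = np.empty(q)
    p = np.empty(q)
    f = 0.0
    for r in range(length):
        for m in range(m_rows):
            for a in range(q):
                logits[a] = h[r, a]
            for j in range(length):
                if j == r:
                    continue
                b = X[m, j]
                row = Jc[r, j, b]
                for a in range(q):
                    logits[a] += row[a]
            mx = logits[0]
            for a in range(1, q):
                if logits[a] > mx:
                    mx = logits[a]
            s = 0.0
            for a in range(q):
                p[a] = np.exp(logits[a] - mx)
                s += p[a]
            xr = X[m, r]
            wm = w[m]
            f -= wm * (logits[xr] - mx - np.log(s))
            inv = wm / s
            for a in range(q):
                p[a] *= inv
            p[xr] -= wm
            for a in range(q):
                gh[r, a] += p[a]
            for j in range(length):
                if j == r:
                    continue
                b = X[m, j]
                row = gJ[r, j, b]
                for a in range(q):
                    row[a] += p[a]
    # L2 penalties (diagonal Jc blocks are zero and stay zero).
    ph = 0.0
    for r in range(length):
        for a in range(q):
            ph += h[r, a] * h[r, a]
            gh[r, a] += 2.0 * lam_h * h[r, a]
    pj = 0.0
    for r in range(length):
        for j in range(length):
            if j == r:
                continue
            for b in range(q):
                for a in range(q):
                    v = Jc[r, j, b, a]
                    pj += v * v
                    gJ[r, j, b, a] += 2.0 * lam_j * v
    f += lam_h * ph + lam_j * pj
    return f, gh, gJ


@njit(cache=True)
def gibbs_sample(h, Jn, nbrs, deg, n_samples, burn_in, thin, seed):
    """Single-site Gibbs sampler with sequential sweep order.

    One sweep updates sites ``0..L-1`` in order from their exact conditional
    distributions.  ``n_samples`` states are recorded every ``thin`` sweeps
    after ``burn_in`` sweeps.  Deterministic for a fixed seed.
    """
    np.random.seed(seed)
    length, q = h.shape
    x = np.empty(length, dtype=np.int8)
    for i in range(length):
        x[i] = np.int8(np.random.randint(0, q))
    out = np.empty((n_samples, length), dtype=np.int8)
    logits = np.empty(q)
    cum = np.empty(q)
    taken = 0
    sweep = 0
    while taken < n_samples:
        for i in range(length):
            for a in range(q):
                logits[a] = h[i, a]
            for d in range(deg[i]):
                j = nbrs[i, d]
                row = Jn[i, d, x[j]]
                for a in range(q):
                    logits[a] += row[a]
            mx = logits[0]
            for a in range(1, q):
                if logits[a] > mx:
                    mx = logits[a]
            s = 0.0
            for a in range(q):
                s += np.exp(logits[a] - mx)
                cum[a] = s
            u = np.random.random() * s
            a = 0
            while a < q - 1 and cum[a] < u:
                a += 1
            x[i] = np.int8(a)
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            out[taken] = x
            taken += 1
    return out
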