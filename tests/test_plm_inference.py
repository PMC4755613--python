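"""Pseudo-likelihood objective, gradient oracle, and fitting behaviour."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize

from ppidca.alignments import LabeledMSA, SequenceWeights, compute_weights
from ppidca.plm_inference import (
    FitConfig,
    PottsModel,
    fit_paired,
    fit_potts,
    pseudo_loglikelihood,
)
from ppidca.matching import MatchResult, PairedMSA
from ppidca.scoring import frobenius_scores, zero_sum_gauge


def random_model(L, q, seed, scale=0.5):
    rng = np.random.default_rng(seed)
    h = rng.normal(scale=scale, size=(L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            g = rng.normal(scale=scale, size=(q, q))
            J[i, j] = g
            J[j, i] = g.T
    return PottsModel(h, J)


def random_msa(M, L, q, seed):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, q, size=(M, L)).astype(np.int8)
    return LabeledMSA(X, [f"s{i}" for i in range(M)],
                      ["A00000"] * M, q=q)


def exact_loglikelihood_fit(msa, weights, lam=1e-4):
    """Brute-force maximum-likelihood oracle: explicit partition sum.

    Only usable for q**L small.  Same L2 penalties as the mean-form fit.
    The model is linear in its parameters, so every state's energy is one
    row of a fixed design matrix and the exact likelihood and its gradient
    are closed-form.
    """
    L, q = msa.length, msa.q
    states = np.array(list(itertools.product(range(q), repeat=L)))
    meff = weights.effective_count
    iu = [(i, j) for i in range(L) for j in range(i + 1, L)]
    n_params = L * q + len(iu) * q * q

    def design(S):
        D = np.zeros((len(S), n_params))
        rows = np.arange(len(S))
        for i in range(L):
            D[rows, i * q + S[:, i]] = 1.0
        for k, (i, j) in enumerate(iu):
            D[rows, L * q + k * q * q + S[:, i] * q + S[:, j]] += 1.0
        return D

    D_states = design(states)
    c_data = design(msa.sequences).T @ weights.weights / meff  # mean features

    def negll(x):
        logw = D_states @ x
        mx = logw.max()
        z = np.exp(logw - mx)
        logz = mx + np.log(z.sum())
        p = z / z.sum()
        f = -(c_data @ x - logz) + lam * np.sum(x ** 2)
        g = -(c_data - D_states.T @ p) + 2 * lam * x
        return f, g

    res = minimize(negll, np.zeros(n_params), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14})
    h = res.x[: L * q].reshape(L, q)
    Jt = res.x[L * q:].reshape(len(iu), q, q)
    J = np.zeros((L, L, q, q))
    for k, (i, j) in enumerate(iu):
        J[i, j] = Jt[k]
        J[j, i] = Jt[k].T
    return PottsModel(h, J)


class TestPseudoLoglikelihood:
    def test_zero_parameters_give_uniform_conditionals(self, tiny_msa):
        L, q = tiny_msa.length, tiny_msa.q
        model = PottsModel(np.zeros((L, q)), np.zeros((L, L, q, q)))
        w = compute_weights(tiny_msa, 0.2)
        val, _, _ = pseudo_loglikelihood(model, tiny_msa, w)
        assert val == pytest.approx(w.effective_count * L * np.log(1 / q))

    def test_gradient_matches_central_finite_differences(self):
        """Finite-difference oracle on an L=3, q=3, M=5 instance."""
        L, q, M = 3, 3, 5
        model = random_model(L, q, seed=1)
        msa = random_msa(M, L, q, seed=2)
        w = SequenceWeights(np.linspace(0.5, 1.0, M), 0.2)
        lam_h, lam_j = 0.02, 0.03
        val, gh, gJ = pseudo_loglikelihood(model, msa, w, lam_h, lam_j)
        eps = 1e-6
        rng = np.random.default_rng(3)
        for _ in range(20):
            i = rng.integers(0, L)
            a = rng.integers(0, q)
            hp = model.h.copy(); hp[i, a] += eps
            hm = model.h.copy(); hm[i, a] -= eps
            vp, _, _ = pseudo_loglikelihood(PottsModel(hp, model.J), msa, w, lam_h, lam_j)
            vm, _, _ = pseudo_loglikelihood(PottsModel(hm, model.J), msa, w, lam_h, lam_j)
            fd = (vp - vm) / (2 * eps)
            assert gh[i, a] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        for _ in range(20):
            i, j = sorted(rng.choice(L, size=2, replace=False))
            a, b = rng.integers(0, q, size=2)
            Jp = model.J.copy(); Jp[i, j, a, b] += eps; Jp[j, i, b, a] += eps
            Jm = model.J.copy(); Jm[i, j, a, b] -= eps; Jm[j, i, b, a] -= eps
            vp, _, _ = pseudo_loglikelihood(PottsModel(model.h, Jp), msa, w, lam_h, lam_j)
            vm, _, _ = pseudo_loglikelihood(PottsModel(model.h, Jm), msa, w, lam_h, lam_j)
            fd = (vp - vm) / (2 * eps)
            assert gJ[i, j, a, b] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_doubling_weights_doubles_unpenalized_objective(self):
        model = random_model(3, 3, seed=4)
        msa = random_msa(6, 3, 3, seed=5)
        w1 = SequenceWeights(np.full(6, 0.5), 0.2)
        w2 = SequenceWeights(np.full(6, 1.0), 0.2)
        v1, _, _ = pseudo_loglikelihood(model, msa, w1)
        v2, _, _ = pseudo_loglikelihood(model, msa, w2)
        assert v2 == pytest.approx(2 * v1)

    def test_dimension_mismatch_rejected(self, tiny_msa):
        model = random_model(3, tiny_msa.q, seed=0)
        w = compute_weights(tiny_msa)
        with pytest.raises(ValueError):
            pseudo_loglikelihood(model, tiny_msa, w)

    def test_objective_is_concave(self):
        """Sampled chords of the unpenalized objective lie below the graph."""
        msa = random_msa(8, 3, 3, seed=6)
        w = compute_weights(msa, 0.2)
        rng = np.random.default_rng(7)
        for trial in range(5):
            m1 = random_model(3, 3, seed=10 + trial)
            m2 = random_model(3, 3, seed=20 + trial)
            v1, _, _ = pseudo_loglikelihood(m1, msa, w)
            v2, _, _ = pseudo_loglikelihood(m2, msa, w)
            t = rng.uniform(0.2, 0.8)
            mid = PottsModel(t * m1.h + (1 - t) * m2.h, t * m1.J + (1 - t) * m2.J)
            vm, _, _ = pseudo_loglikelihood(mid, msa, w)
            assert vm >= t * v1 + (1 - t) * v2 - 1e-10


class TestFitPotts:
    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_potts(random_msa(1, 4, 3, 0))
        with pytest.raises(ValueError):
            fit_potts(random_msa(5, 1, 3, 0))

    def test_length_guard(self):
        msa = random_msa(2, 1001, 2, 0)
        with pytest.raises(ValueError, match="1000"):
            fit_potts(msa)

    def test_independent_columns_show_no_coupling_signal(self):
        """Couplings on independent data stay near the permutation-null floor."""
        rng = np.random.default_rng(11)
        X = rng.integers(0, 4, size=(300, 6)).astype(np.int8)
        msa = LabeledMSA(X, [f"s{i}" for i in range(300)], ["A00000"] * 300, q=4)
        model = fit_potts(msa, FitConfig(lambda_J=0.05))
        norms = [np.linalg.norm(zero_sum_gauge(model.J[i, j]))
                 for i in range(6) for j in range(i + 1, 6)]
        # permutation of rows per column is another independent draw: the
        # two norm distributions must be on the same scale
        Xp = np.column_stack([rng.permutation(X[:, c]) for c in range(6)])
        msap = LabeledMSA(Xp.astype(np.int8), msa.species, msa.accessions, q=4)
        modelp = fit_potts(msap, FitConfig(lambda_J=0.05))
        normsp = [np.linalg.norm(zero_sum_gauge(modelp.J[i, j]))
                  for i in range(6) for j in range(i + 1, 6)]
        assert max(norms) < 10 * max(normsp)

    def test_covarying_pair_has_largest_coupling(self):
        """Two perfectly covarying columns dominate all other pairs."""
        rng = np.random.default_rng(12)
        M, L, q = 400, 5, 4
        X = rng.integers(0, q, size=(M, L)).astype(np.int8)
        X[:, 3] = X[:, 1]  # deterministic covariation between columns 1 and 3
        msa = LabeledMSA(X, [f"s{i}" for i in range(M)], ["A00000"] * M, q=q)
        model = fit_potts(msa)
        norms = {(i, j): np.linalg.norm(zero_sum_gauge(model.J[i, j]))
                 for i in range(L) for j in range(i + 1, L)}
        assert max(norms, key=norms.get) == (1, 3)

    def test_fit_is_deterministic(self):
        msa = random_msa(50, 4, 3, seed=13)
        m1 = fit_potts(msa)
        m2 = fit_potts(msa)
        assert np.array_equal(m1.h, m2.h)
        assert np.array_equal(m1.J, m2.J)

    def test_symmetric_and_asymmetric_agree_on_ranking(self):
        rng = np.random.default_rng(14)
        M, L, q = 300, 4, 3
        X = rng.integers(0, q, size=(M, L)).astype(np.int8)
        flip = rng.random(M) < 0.9
        X[flip, 2] = (X[flip, 0] + 1) % q  # strong 0-2 covariation
        msa = LabeledMSA(X, [f"s{i}" for i in range(M)], ["A00000"] * M, q=q)
        ma = fit_potts(msa, FitConfig(symmetric=False))
        ms = fit_potts(msa, FitConfig(symmetric=True))
        def ranking(m):
            return sorted(
                ((i, j) for i in range(L) for j in range(i + 1, L)),
                key=lambda p: -np.linalg.norm(zero_sum_gauge(m.J[p])))
        assert ranking(ma)[0] == ranking(ms)[0] == (0, 2)

    def test_pseudo_likelihood_matches_exact_ml_at_large_m(self):
        """On an enumerable L=2, q=3 model both estimators agree closely."""
        truth = random_model(2, 3, seed=15, scale=0.8)
        probs = np.zeros((3, 3))
        for a in range(3):
            for b in range(3):
                probs[a, b] = np.exp(truth.h[0, a] + truth.h[1, b]
                                     + truth.J[0, 1, a, b])
        probs /= probs.sum()
        rng = np.random.default_rng(16)
        flat = rng.choice(9, size=20000, p=probs.ravel())
        X = np.column_stack([flat // 3, flat % 3]).astype(np.int8)
        msa = LabeledMSA(X, [f"s{i}" for i in range(len(X))],
                         ["A00000"] * len(X), q=3)
        w = SequenceWeights(np.ones(len(X)), 1.0)
        plm = fit_potts(msa, FitConfig(lambda_h=1e-4, lambda_J=1e-4,
                                       identity_threshold=1.0, max_iter=500,
                                       tol=1e-6), weights=w)
        ml = exact_loglikelihood_fit(msa, w)
        g_plm = zero_sum_gauge(plm.J[0, 1])
        g_ml = zero_sum_gauge(ml.J[0, 1])
        rel = np.linalg.norm(g_plm - g_ml) / np.linalg.norm(g_ml)
        assert rel < 0.1


class TestFitPaired:
    def _paired(self, M=60, la=4, lb=6, seed=17):
        msa = random_msa(M, la + lb, 5, seed)
        return PairedMSA(msa, la, MatchResult())

    def test_partition_recorded(self):
        paired = self._paired()
        model = fit_paired(paired, FitConfig(max_iter=5))
        assert model.length == 10
        assert model.partition == [4, 10]

    def test_partition_does_not_alter_parameters(self):
        paired = self._paired()
        m1 = fit_paired(paired, FitConfig(max_iter=10))
        m2 = fit_potts(paired.msa, FitConfig(max_iter=10))
        assert np.allclose(m1.h, m2.h)
        assert np.allclose(m1.J, m2.J)

    def test_shuffled_partner_loses_inter_coupling(self):
        """Row-shuffling the B half of a covarying pair kills inter signal."""
        rng = np.random.default_rng(18)
        M, la, lb, q = 500, 3, 3, 4
        X = rng.integers(0, q, size=(M, la + lb)).astype(np.int8)
        X[:, la] = X[:, 0]  # column 0 (A) covaries with column 3 (B)
        msa = LabeledMSA(X, [f"s{i}" for i in range(M)], ["A00000"] * M, q=q)
        model = fit_paired(PairedMSA(msa, la, MatchResult()))
        Xs = X.copy()
        Xs[:, la:] = Xs[rng.permutation(M), la:]
        msas = LabeledMSA(Xs, msa.species, msa.accessions, q=q)
        models = fit_paired(PairedMSA(msas, la, MatchResult()))
        def max_inter(m):
            return max(np.linalg.norm(zero_sum_gauge(m.J[i, j]))
                       for i in range(la) for j in range(la, la + lb))
        assert max_inter(models) < 0.5 * max_inter(model)


class TestModelContainer:
    def test_save_load_round_trip(self, tmp_path):
        model = random_model(3, 4, seed=19)
        model.partition = [2, 3]
        p = tmp_path / "model.npz"
        model.save(p)
        back = PottsModel.load(p)
        assert np.array_equal(back.h, model.h)
        assert np.array_equal(back.J, model.J)
        assert back.partition == [2, 3]

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            PottsModel(np.zeros((3, 2)), np.zeros((3, 3, 2, 2)), partition=[5])
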