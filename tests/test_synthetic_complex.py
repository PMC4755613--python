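"""Artificial complex construction and Potts sequence simulation."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from ppidca.plm_inference import PottsModel
from ppidca.scoring import zero_sum_gauge
from ppidca.synthetic_complex import (
    GeneratorModel,
    assign_couplings,
    banded_contact_map,
    build_complex,
    coupling_pool_from_model,
    default_coupling_pool,
    paralogize,
    sample_msa,
    scaled_demo_complex,
    split_families,
)


def boltzmann_probs(model: PottsModel) -> dict[tuple, float]:
    """Exact enumeration oracle: Boltzmann probabilities for tiny models."""
    L, q = model.length, model.q
    logw = {}
    for s in itertools.product(range(q), repeat=L):
        e = sum(model.h[i, s[i]] for i in range(L))
        e += sum(model.J[i, j, s[i], s[j]]
                 for i in range(L) for j in range(i + 1, L))
        logw[s] = e
    mx = max(logw.values())
    z = sum(np.exp(v - mx) for v in logw.values())
    return {s: np.exp(v - mx) / z for s, v in logw.items()}


def tiny_model(L=3, q=2, seed=0, scale=0.8) -> PottsModel:
    rng = np.random.default_rng(seed)
    h = rng.normal(scale=scale, size=(L, q))
    J = np.zeros((L, L, q, q))
    for i in range(L):
        for j in range(i + 1, L):
            g = rng.normal(scale=scale, size=(q, q))
            J[i, j] = g
            J[j, i] = g.T
    return PottsModel(h, J)


class TestBuildComplex:
    def test_banded_template_counts(self):
        assert len(banded_contact_map(10, 6)) == 39
        assert len(banded_contact_map(10, 9)) == 45

    def test_inter_contact_counts_per_edge(self):
        template = {(i, j) for i in range(20) for j in range(i + 1, i + 6)
                    if j < 20}
        n_intra = len(template)
        spec = build_complex(template, 20, n_proteins=5, inter_density=0.1)
        assert len(spec.edges) == 5  # circular pentagon
        for e in spec.edges:
            assert len(spec.inter[e]) == round(0.1 * n_intra)

    def test_circular_topology_edges(self):
        spec = scaled_demo_complex()
        assert spec.edges == [(0, 1), (0, 4), (1, 2), (2, 3), (3, 4)]
        assert not spec.is_edge(0, 2) and not spec.is_edge(1, 3)
        assert spec.total_length == 50

    def test_zero_inter_contacts_rejected(self):
        with pytest.raises(ValueError, match="undetectable"):
            build_complex({(0, 1)}, 4, inter_density=0.1)

    def test_seeded_determinism(self):
        s1 = build_complex(banded_contact_map(8, 3), 8, seed=9)
        s2 = build_complex(banded_contact_map(8, 3), 8, seed=9)
        assert s1.inter == s2.inter


class TestAssignCouplings:
    def test_single_matrix_pool_replicates_everywhere(self):
        spec = scaled_demo_complex()
        mat = np.arange(441, dtype=float).reshape(21, 21)
        gen = assign_couplings(spec, [mat], seed=0)
        off = spec.offsets()
        for p in range(spec.n_proteins):
            for i, j in spec.intra[p]:
                assert np.array_equal(gen.model.J[off[p] + i, off[p] + j], mat)

    def test_couplings_only_on_contacts(self):
        spec = scaled_demo_complex()
        gen = assign_couplings(spec, [np.ones((21, 21))], seed=0)
        contacts = spec.global_contacts()
        L = spec.total_length
        for i in range(L):
            for j in range(i + 1, L):
                has = bool(np.any(gen.model.J[i, j]))
                assert has == ((i, j) in contacts)

    def test_zero_pool_gives_independent_sites(self):
        spec = scaled_demo_complex()
        gen = assign_couplings(spec, [np.zeros((21, 21))], seed=0)
        assert not gen.model.J.any()

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            assign_couplings(scaled_demo_complex(), [], seed=0)

    def test_generator_norms_match_pool_distribution(self):
        """Placed coupling norms are drawn from the pool's norm set."""
        pool = list(default_coupling_pool())
        pool_norms = sorted({round(float(np.linalg.norm(zero_sum_gauge(m))), 6)
                             for m in pool})
        spec = scaled_demo_complex()
        gen = assign_couplings(spec, pool, seed=3)
        placed = []
        for (i, j) in spec.global_contacts():
            placed.append(round(float(np.linalg.norm(
                zero_sum_gauge(gen.model.J[i, j]))), 6))
        assert set(placed) <= set(pool_norms)
        # two-sample check: placed norms cover the pool's spread
        assert ks_2samp(placed, pool_norms).pvalue > 1e-4


class TestGibbsSampler:
    def test_uniform_target_for_zero_model(self):
        model = PottsModel(np.zeros((4, 3)), np.zeros((4, 4, 3, 3)))
        msa = sample_msa(model, 30000, sweeps_between_samples=1, burn_in=10,
                         seed=1)
        for site in range(4):
            counts = np.bincount(msa.sequences[:, site], minlength=3)
            assert chisquare(counts).pvalue > 1e-4

    def test_matches_exact_boltzmann_distribution(self):
        """Chi-square against brute-force enumeration on L=3, q=2."""
        model = tiny_model(L=3, q=2, seed=4)
        probs = boltzmann_probs(model)
        msa = sample_msa(model, 50000, sweeps_between_samples=10, burn_in=200,
                         seed=5)
        keys = sorted(probs)
        observed = np.zeros(len(keys))
        index = {k: i for i, k in enumerate(keys)}
        for row in msa.sequences:
            observed[index[tuple(row)]] += 1
        expected = np.array([probs[k] for k in keys]) * 50000
        assert chisquare(observed, expected).pvalue > 0.01

    def test_detailed_balance_of_single_site_kernel(self):
        """Each per-site conditional update leaves the Boltzmann distribution
        invariant (transition-matrix check on an enumerable model)."""
        model = tiny_model(L=3, q=3, seed=6, scale=0.6)
        probs = boltzmann_probs(model)
        states = sorted(probs)
        pi = np.array([probs[s] for s in states])
        idx = {s: i for i, s in enumerate(states)}
        L, q = model.length, model.q
        for site in range(L):
            K = np.zeros((len(states), len(states)))
            for s in states:
                logits = model.h[site].copy()
                for j in range(L):
                    if j != site:
                        logits += model.J[site, j, :, s[j]]
                p = np.exp(logits - logits.max())
                p /= p.sum()
                for a in range(q):
                    t = list(s)
                    t[site] = a
                    K[idx[s], idx[tuple(t)]] += p[a]
            assert np.allclose(pi @ K, pi, atol=1e-12)

    def test_seeded_determinism(self):
        model = tiny_model()
        m1 = sample_msa(model, 50, seed=7)
        m2 = sample_msa(model, 50, seed=7)
        assert np.array_equal(m1.sequences, m2.sequences)

    def test_input_validation(self):
        model = tiny_model()
        with pytest.raises(ValueError):
            sample_msa(model, 0)
        with pytest.raises(ValueError):
            sample_msa(model, 5, sweeps_between_samples=0)


class TestFamilies:
    def test_split_families_recovers_columns_and_offsets_accessions(self):
        spec = scaled_demo_complex()
        gen = assign_couplings(spec, [np.zeros((21, 21))], seed=0)
        joint = sample_msa(gen, 20, sweeps_between_samples=1, burn_in=1, seed=0)
        fams = split_families(joint, spec)
        assert len(fams) == 5
        for p, fam in enumerate(fams):
            start, stop = spec.regions()[p]
            assert np.array_equal(fam.sequences, joint.sequences[:, start:stop])
        from ppidca.matching import accession_ordinal
        o0 = accession_ordinal(fams[0].accessions[0])
        o1 = accession_ordinal(fams[1].accessions[0])
        assert o1 - o0 == 1  # adjacent accessions emulate co-operonic genes

    def test_paralogize_creates_two_member_species(self):
        spec = scaled_demo_complex()
        gen = assign_couplings(spec, [np.zeros((21, 21))], seed=0)
        joint = sample_msa(gen, 40, sweeps_between_samples=1, burn_in=1, seed=0)
        fams = paralogize(split_families(joint, spec), 0.5, seed=1)
        counts = {}
        for sp in fams[0].species:
            counts[sp] = counts.get(sp, 0) + 1
        assert set(counts.values()) <= {1, 2}
        assert 2 in counts.values()


def test_default_pool_is_deterministic_and_nontrivial():
    p1 = default_coupling_pool()
    assert len(p1) == 8
    norms = [np.linalg.norm(zero_sum_gauge(m)) for m in p1]
    assert min(norms) > 0.5  # pool carries real coupling signal
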