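# ppidca

Protein–protein interaction partner prediction by inter-protein
Direct-Coupling Analysis (DCA).

Given multiple sequence alignments of two protein families, which pairs of
families interact — and through which residues?  `ppidca` answers both
questions from sequences alone, for researchers studying bacterial protein
complexes and interaction networks where paired alignments can be built by
genomic co-localization:

1. **Matching.**  Two family alignments are concatenated row-wise so that
   each row holds one putatively interacting protein pair.  Within each
   species, paralogs are paired by solving the linear assignment problem
   that minimizes the total *genomic distance* between partners,
   approximated by the distance between database accession numbers
   (co-operonic genes tend to be deposited under adjacent accessions);
   matched pairs farther apart than a threshold are discarded.
2. **Inference.**  The paired alignment D over sequences
   (x, x′) of length L = L_A + L_B is modelled by a Potts model
   (pairwise Markov random field) over q = 21 states (20 amino acids + gap):

       P(x) = (1/Z) exp( Σ_{i<j} J_ij(x_i, x_j) + Σ_i h_i(x_i) )

   whose parameters are estimated by L2-regularized, sequence-reweighted
   *pseudo-likelihood maximization* (the plmDCA approach) — the partition
   function Z is never evaluated.
3. **Scoring.**  Each site pair gets the APC-corrected Frobenius norm
   F_ij of its coupling matrix in the zero-sum gauge.  The *interaction
   score* of a protein pair is the mean of the k = 4 largest F_ij over
   inter-protein site pairs; pairs are ranked by it.
4. **Validation.**  A built-in simulator reproduces an artificial
   5-protein ring complex: a ground-truth Potts model with couplings only
   on (intra- and inter-protein) contacts, sampled by Gibbs MCMC, so the
   whole pipeline can be exercised end to end with known truth.  A
   `structures` module derives contact-map ground truth (8 Å heavy-atom
   cutoff) from PDB/mmCIF files for real complexes.

## Worked example

Recover the ring topology of the artificial complex from sampled sequences
(five proteins of length 10; protein i touches i±1 and nothing else):

```python
import ppidca as pp
from ppidca.evaluation import infer_network_paired
from ppidca.synthetic_complex import (assign_couplings, default_coupling_pool,
                                      sample_msa, scaled_demo_complex,
                                      split_families)

spec = scaled_demo_complex(seed=1)          # 5 proteins x 10 residues, ring
gen = assign_couplings(spec, default_coupling_pool(), seed=1)
joint = sample_msa(gen, 20000, seed=1)      # joint MSA from the Potts model
fams = dict(zip("P1 P2 P3 P4 P5".split(), split_families(joint, spec)))
net = infer_network_paired(fams)            # match, fit, score all 10 pairs
print(net.ranking()[["protein_a", "protein_b", "score", "depth"]])
```

Output (about a minute on one CPU):

```
protein_a protein_b     score  depth
       P4        P5  0.039416  20000
       P1        P5  0.035971  20000
       P1        P2  0.028849  20000
       P2        P3  0.027685  20000
       P3        P4  0.022738  20000
       P1        P4  0.002338  20000
       P2        P5 -0.000084  20000
       P1        P3 -0.000867  20000
       P2        P4 -0.002196  20000
       P3        P5 -0.005042  20000
```

All five true ring edges (P1–P2, P2–P3, P3–P4, P4–P5, P1–P5) rank above all
five non-edges, with an order-of-magnitude score gap.  The score is the mean
of the 4 largest APC-corrected inter-protein residue couplings, so ~0.03
here means a handful of residue pairs co-evolve strongly; non-edges sit at
the noise level ~0.  At M = 4000 sequences — closer to what current
databases provide per bacterial protein pair — the same experiment ranks
only three true edges in the top five: recovery hinges on alignment depth.

The same steps run from the shell via the `ppidca` command
(`simulate`, `match`, `fit`, `score`, `contacts`, `evaluate`).

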