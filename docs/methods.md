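# Methods

## Sequence model and inference

Aligned sequences x = (x_1 … x_L) over q = 21 states (the 20 amino acids in
alphabetical order, preceded by the gap, which is treated as an ordinary
state) are modelled by a Potts model

    P(x) = (1/Z) exp( Σ_{i<j} J_ij(x_i, x_j) + Σ_i h_i(x_i) ).

For a paired alignment of two families the same model applies to the
concatenation; its couplings decompose into two intra-protein blocks and an
inter-protein block, and only the inter block enters interaction scoring.
Non-standard residue codes (B, J, O, U, X, Z) are mapped to the gap state:
a 21-state model has nowhere else to put them, and they are rare enough not
to warrant extra states.

Parameters are estimated by maximizing the reweighted, L2-penalized
pseudo-likelihood — the product over sites of each site's conditional
probability given the rest — which sidesteps Z entirely.  The default route
is the *asymmetric* variant of the plmDCA family: L independent multinomial
logistic regressions (site r on all other sites), run as one concave joint
optimization, followed by the symmetrization J_ij ← (J^(i)_ij + J^(j)_jiᵀ)/2.
A symmetric-parameterization variant (`FitConfig(symmetric=True)`) exists
for small problems and cross-checks; on strongly covarying test data both
produce the same coupling ranking.

Numerical choices:

* **Objective scale.**  The fitting objective is the weighted *mean*
  negative log-pseudo-likelihood plus λ_h‖h‖² + λ_J‖J‖², with
  λ_h = λ_J = 0.01 on that per-effective-sequence scale — the convention in
  which the usual plmDCA defaults are stated.  The standalone
  `pseudo_loglikelihood` function reports the weighted-sum form (so the
  objective is linear in the weights), with separate optional penalties.
* **Reweighting.**  Sequence m gets weight 1/(number of sequences within
  20 % normalized Hamming distance of m, itself included); the weights are
  always computed on the alignment actually fitted, because matching can
  duplicate rows.  The 0.2 threshold is the published plmDCA default and is
  user-overridable.
* **Optimizer.**  L-BFGS-B, gradient supplied analytically by a numba
  kernel; stopping at projected-gradient ∞-norm 1e-3 (mean-objective
  scale), at most 100 iterations.  Fields start at smoothed log column
  frequencies and couplings at zero: the penalized objective is strictly
  concave, so the optimum is initialization-independent and the
  deterministic warm start only saves iterations.  With the default ridge
  the fit typically converges in well under 20 iterations.
* **Shrinkage.**  With q = 21 and near-uniform marginals the per-cell
  Fisher information (~1/q²) is far below λ = 0.01, so fitted couplings are
  shrunk several-fold relative to the generating ones.  This is shared by
  all plmDCA-type estimators at these settings; rankings, which are what
  the scores feed, are unaffected.  The consistency check
  (`potts_recovery_error`) therefore uses λ = 1e-5: a consistency statement
  requires vanishing regularization.
* **Guard.**  Alignment widths above L = 1000 are refused: the parameter
  count grows as L²q² and pseudo-likelihood maximization beyond that width
  is impractical on a single machine.

## Scoring

Couplings are only defined up to per-site gauge shifts, so each coupling
matrix is first put in the zero-sum gauge (all row and column means zero);
its Frobenius norm is then a well-defined co-evolution strength.  For
21-state models the gap row/column is excluded from the norm (alignment
coverage artefacts, not co-evolution; `exclude_gap=False` reverses this for
sensitivity analysis).  The average-product correction
F_apc(i,j) = F(i,j) − F̄_i F̄_j / F̄ (off-diagonal means) removes background
shared across rows/columns — conservation and phylogenetic signal.

A protein pair's interaction score is the mean of the k = 4 largest
APC-corrected inter-protein scores; any k between 1 and 6 gives nearly the
same rankings on the synthetic complex, and if fewer than k inter pairs
exist they are all averaged.  Ranking ties break lexicographically by pair
id so outputs are bit-reproducible.

## Matching

The genomic distance between two sequences of one species is approximated
by |ordinal(a) − ordinal(b)| of their accession strings under a positional
base-36 encoding ([0-9A-Z]); 6- and 10-character accession formats are
distinct numbering schemes and are mutually incomparable (infinite
distance).  This proxy is a documented, replaceable policy object — any
`distance(acc_a, acc_b)` callable can be supplied.  Per species, the
rectangular linear assignment problem minimizing total distance is solved
exactly (scipy); among equal-cost matchings the lexicographically smallest
pair-index list is selected by fixing pairs in order and re-solving, so
matchings are deterministic.  Matched pairs beyond the distance threshold
are then discarded; the threshold is applied after solving the assignment.
No default threshold is baked in — it depends on the accession scheme and
deposition habits — so `sweep_thresholds` reports retained-pair counts
across candidate values for calibration.  Threshold 0 reduces to keeping
only species without paralogs (`unique_only`), and
`randomized_within_species` scrambles the matching inside each species as a
negative control.

## Synthetic complex and sampler

The validation testbed is a ring of N = 5 structurally identical proteins:
protein i interacts with i±1 (mod 5) and no one else.  The scaled study
conditions are per-protein length 10 with a separation-band intra-contact
template (all pairs within 6 positions; 39 contacts — a compact short
peptide places nearly every nearby residue pair within the 8 Å heavy-atom
cutoff), and each interface receives round(0.1 × 39) = 4 inter-protein
contacts placed uniformly at random, mirroring how sparse real interfaces
are relative to protein cores.  Contacting site pairs carry coupling
matrices drawn from a *pool*; all other couplings are exactly zero; fields
default to zero.

The default pool is built by fitting the package's own inference to a
bundled synthetic 400 × 12 family alignment (itself sampled from a Potts
model with six coupled column pairs) and keeping the 8 strongest coupling
matrices; their zero-sum-gauge norms land in the ~1.6–2.2 range typical of
strong inferred contacts, so generator couplings have the value
distribution of inferred ones rather than idealized shapes.  Any list of
q × q matrices can be supplied instead (`assign_couplings(spec, pool)`),
e.g. couplings fitted from a real family.  Inter-contact matrices are
sampled from the pool uniformly with replacement.

Joint alignments are drawn by single-site Gibbs sampling in sequential
sweep order — each update samples a site from its exact conditional, which
leaves the Boltzmann distribution invariant (verified by transition-matrix
enumeration on small models, and by chi-square agreement with exact
enumeration at 50 000 samples).  Defaults: 1000 burn-in sweeps, 10 sweeps
between recorded samples, both configurable; a Metropolis check of the same
distributions is unnecessary given the exact-enumeration tests.  The
generator is i.i.d. by construction: it has no phylogeny, no biased species
sampling, and intra- and inter-protein couplings of the same strength.
Passing recovery tests on it therefore bounds what the method could achieve
on ideal data of the same size — real alignments carry phylogenetic
correlations that can only degrade the signal — and says nothing about
alignment-construction quality, which this package does not address.

## Recovery experiments and what they show

`ppidca.pipeline.ring_recovery_experiment` runs, per seed: sample a joint
MSA (M = 500 and M = 20 000), split it into five family alignments with
per-species accessions that emulate co-operonic deposition, re-pair them by
genomic-proximity matching, and infer the network with both strategies —
*paired* (one model per protein pair, the generally applicable route) and
*combined* (one model over all five proteins, feasible only for short
complexes).  At M = 20 000 all five ring edges outrank all five non-edges
in every seed tried and residue-level prediction is essentially perfect
(top-10 intra predictions per protein all true; top-20 inter predictions
≥ 99 % true on average); at M = 500 the ranking is unreliable (AUC ≈ 0.66).
Non-edge pairs score higher under the paired strategy than the combined one
when measured on raw (pre-APC) norms: correlations between, say, P1 and P3
travel through the ring's paths and must be absorbed into direct P1–P3
couplings when the pair is modelled alone.  APC-corrected scores are not
comparable across different fits (APC recenters each fit's own background),
so this comparison uses raw norms.

One validation check fails at these study conditions and is retained as a
negative result: the *fully* column-shuffled noise floor.  Shuffling every
column independently and re-running the paired strategy leaves raw norm
noise of identical spread (std ≈ 0.010) as in structured fits, but APC can
no longer remove it — with real signal present, cross-pair score variation
is site-driven (row/column structured, exactly what the rank-1 APC term
models; residual noise ≈ 0.002), whereas on fully-null data the variation
is exchangeable and the maximum APC residual over the ~1000 inter cells
reaches ≈ 0.03, above the weakest true edge's interaction score (0.016, a
top-4 mean over an interface of only 4 true contacts under several-fold
ridge shrinkage).  Within any structured fit the separation is wide
(non-edges ≤ 0.0034); the lesson is that APC scores are comparable within a
fit, not across fits of unrelated data.

## Structure ground truth

Contacts are residue pairs whose minimum heavy-atom (non-hydrogen) distance
is strictly below the cutoff (8 Å default); nucleic-acid chains are
excluded by default; disordered atoms resolve to their highest-occupancy
location and only the first model of multi-model files is read.  Sequence-
separation filtering (≥ 5) is applied only when evaluating intra-protein
*predictions*, not to global contact totals; both are exposed as flags.  A
protein pair is declared interacting when it has at least one inter-protein
contact.  Mapping alignment columns to residue numbers is the caller's
responsibility (a mapping table), since alignment construction is out of
scope.

## Known limitations

* The accession-distance proxy is a stand-in for true genomic distance;
  it is deliberately pluggable.
* Interaction scores rank pairs but carry no significance threshold; the
  score distributions of interacting and non-interacting pairs overlap
  except in their tails.
* The simulator's i.i.d. assumption means test performance upper-bounds
  real-data performance at equal alignment depth.
* Matching quality is not inferred jointly with couplings; covariation-
  maximizing matching is out of scope.
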