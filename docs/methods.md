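# Methods

`streptophylo` is a desk-scale implementation of the phylogenomic workflow
used to place streptophyte algae relative to land plants: per-gene
ortholog-congruence screening, chimera/occupancy-filtered supermatrix
assembly, maximum-likelihood and Bayesian tree inference under
site-homogeneous and site-heterogeneous protein models, bootstrap and
two-chain convergence support measures, cross-validation model comparison,
and compositional-bias diagnostics (amino-acid PCA and Dayhoff 6-state
recoding).  This note records the models, the estimation choices, the
synthetic-data generator's assumptions, and the limits of what the test
suite demonstrates.

## Substitution models

All models are continuous-time reversible Markov chains on the 20
amino-acid states (or a recoded alphabet).  A model is

* a shared symmetric exchangeability matrix `e`,
* one or more stationary frequency profiles `pi_c` with mixture weights
  `w_c`,
* a discrete-gamma distribution of site rates (C equal-probability
  categories, category rate = mean of the quantile slice, mean rate 1;
  default C = 4).

Per class the generator is `Q_ij = e_ij pi_j` (i != j), rescaled to one
expected substitution per site at stationarity.  The named families are:

| name     | exchangeabilities      | frequencies           |
|----------|------------------------|-----------------------|
| poisson  | uniform                | uniform               |
| lg       | bundled LG constants   | +F (empirical) or LG  |
| gtr      | estimated              | +F (empirical)        |
| cat      | uniform                | k estimated profiles  |
| catgtr   | estimated (shared)     | k estimated profiles  |

The LG rates and frequencies are shipped as a PAML-layout text file
(`data/lg.dat`, the published Le & Gascuel 2008 values).

**Finite-mixture CAT.** The site-heterogeneous families are finite
mixtures with a fixed class count (default 10), not the Dirichlet-process
construction of the original CAT model.  Profiles are fitted by EM over
site-class posterior responsibilities.  The M-step reweights *observed*
residue counts per column by the responsibilities (plus a 0.5 pseudocount)
instead of computing full ancestral-state expectations; this is an
approximation that is fast, monotone in practice, and sufficient to
express the site-heterogeneity contrast the analysis needs.  Class
weights are updated from the responsibilities; profile initialization
draws residue-count vectors of randomly chosen columns (seed-controlled).

**GTR estimation.** Exchangeabilities are estimated by an
expected-sufficient-statistics EM: for every edge, mixture class and rate
category the engine computes the posterior joint distribution of the edge's
endpoint states, converts it to expected transition counts `C_ij` and
state-occupancy times `T_i` through the eigendecomposition integral
`J_kl(t) = (e^{l_k t} - e^{l_l t}) / (l_k - l_l)`, and updates
`e_ij <- (C_ij + C_ji) / (T_i pi_j + T_j pi_i)` with empirical frequencies
held fixed.  The E-step is verified against numerical quadrature in the
test suite.  Because the updated matrix is renormalized to unit expected
rate, exchangeability updates are interleaved with branch-length passes.

## Likelihood engine

Sites are compressed to unique columns with multiplicities.  The pruning
recursion keeps directional messages on every edge (subtree partials,
their push-through to the parent, and outside partials), with per-node
rescaling and natural-log bookkeeping, so that

* the total log-likelihood is a cheap read-out at the root,
* the likelihood as a function of a *single* branch length is a
  one-dimensional function evaluable in O(patterns x states) — branch
  lengths are optimized by Brent's method in a parent-before-children
  sweep with incremental message updates (each 1-D optimization is exact
  given the other current lengths, so the trace is non-decreasing),
* every NNI rearrangement is scored by recombining four cached messages
  across the central edge and re-optimizing only that edge's length.

Gaps and the ambiguity codes B, Z, X (plus `?`, `-`, `*`, `.`) are fully
missing states (partial likelihood one over all states).  Branch lengths
are clamped to [1e-8, 20].  The gamma shape is fitted by Brent on the log
scale in [0.05, 50].  Tolerances: branch-length pass convergence 1e-6 in
log-likelihood; per-edge Brent tolerance 1e-7.

Correctness anchors: exhaustive enumeration over internal-state
assignments on small trees (<= 1e-8 agreement), the closed-form
two-sequence Poisson likelihood, invariance under re-rooting (pulley
principle), invariance under splitting a mixture class, and exact
lumpability of the uniform Poisson chain onto the six Dayhoff groups.

## Tree search, bootstrap and MCMC

Starting trees are neighbor joining on maximum-likelihood pairwise
distances (Brent on the pairwise likelihood of the joint residue-pair
counts).  Search is greedy NNI hill-climbing: all rearrangements are
scored from cached messages, the best strictly improving move is applied,
followed by a quick branch-length pass; ties are broken deterministically.
No SPR/TBR.

The nonparametric bootstrap resamples columns by drawing multinomial
weights over the site patterns (equivalent to column resampling, but
pattern compression is preserved); each replicate gets its own NJ start
and NNI search.  Substitution-model parameters are held at the full-data
estimates across replicates (an empirical-Bayes shortcut); branch lengths
and topology are re-inferred.  Supports are the percentage of replicate
trees containing each ML-tree bipartition.

The MCMC samples topology (uniform random NNI proposals) and branch
lengths (multiplier proposals, exponential prior with mean 0.1) at fixed
substitution-model parameters, again an empirical-Bayes shortcut that the
run report flags.  One cycle is one topology proposal plus one multiplier
proposal per branch.  Two independent chains start from random
topologies; convergence is summarized by the maximum absolute difference
in bipartition frequencies between chains after burn-in, with >= 0.1
flagged as non-converged (the conventional threshold).  Posterior
probabilities come from the pooled post-burn-in samples.

## Supermatrix assembly and screening

Chimeric OTUs merge closely related taxa by whole-gene donation: per gene
the highest-priority source taxon with data donates its entire sequence
(never intra-gene splicing).  Occupancy filtering keeps genes with at
most `max_missing` absent taxa (default 16, the study's threshold for 46
taxa).  Genes are concatenated in lexicographic id order; absent blocks
are filled with `?`; partitions are 0-based half-open internally and
1-based closed in the emitted partition file.

The congruence screen infers one ML tree with bootstrap supports per gene
(on its data-bearing taxa), prunes the reference tree to those taxa, and
flags every gene-tree bipartition with support >= 70% that is pairwise
incompatible with the restricted reference.  A gene is discarded only if
no *single* NNI of its tree removes all supported conflicts (supports
travel with persisting bipartitions; the one new split an NNI creates has
unknown support and cannot itself conflict).  Raising the threshold can
only discard fewer genes; per-gene bootstrap seeds derive from the gene id
so results are invariant to input order.

## Cross-validation

Columns are split 9/10 training : 1/10 test, uniformly at random per
replicate.  Each model's free parameters (branch lengths, gamma shape,
empirical frequencies, exchangeabilities and/or profiles as the family
requires) are fitted on the training columns with the topology fixed at
the reference tree, frozen, and used to score the test columns.  Reported
is the mean +/- sample SD (n-1) of per-replicate differences, positive
favouring the first model.  This is a plug-in scheme: the original
procedure integrates over a posterior rather than plugging in point
estimates, so full-data score magnitudes are approximated, not matched.
Topology is never re-searched inside CV (re-searching would be
cluster-scale and adds search noise).

## Composition diagnostics

The composition matrix holds per-taxon state frequencies over non-missing
cells only.  PCA is covariance PCA of the column-centered matrix (a
correlation option exists); axis signs are fixed by making each axis's
largest-magnitude loading positive.  The per-taxon heterogeneity score is
the Euclidean distance from the mean composition row.  Dayhoff recoding
maps the 20 amino acids onto the six classical groups AGPST / DENQ / HKR
/ ILMV / FWY / C (bundled as an overridable table); recoded alignments
drive the same likelihood machinery with K = 6.

## Synthetic-data generator

The generator is the package's stand-in for the study's EST-derived
alignments and defines the conditions under which the pipeline is tested:

* **Forward simulation** draws a mixture class and gamma category per
  site, a root state from the class profile, and evolves states along each
  branch; lineage rate multipliers scale branch lengths inside a clade
  (clock-free), emulating a fast-evolving clade at about twice the
  background rate.
* **Compositional shifts** blend the emission on terminal branches with a
  biased target profile — a deliberate stationarity violation mimicking
  compositionally deviant taxa.
* **Study-shaped datasets** default to 46 taxa x 129 genes with lognormal
  gene lengths (median 235 columns, sigma 0.35, totalling ~30k positions)
  and whole-gene taxon dropout.  Per-gene missing-taxon counts are
  binomial, truncated at the occupancy cap (16 of 46, scaled for other
  taxon counts), with the success probability calibrated numerically so
  the realized global missing fraction hits the 30% target (+/- 0.02).
  The dropout process is invented — the real per-gene occupancy pattern is
  unpublished — and is not claimed to match it.
* **Paralogs** are injected by regrafting one taxon at least three edges
  away (backbone unchanged, so the conflict is deep but attributable to
  one row) and then *conditionally* re-sampling that taxon's sequence
  given all other rows under the regrafted topology: the posterior state
  distribution at the attachment node is computed by pruning, a state is
  drawn per site and evolved down the pendant branch.  An unconditional
  redraw would be independent of the other rows and carry no placement
  signal.  The injected row is never masked by dropout.  The clean-recovery
  and screen scenarios floor simulated branch lengths (0.03 / 0.04) so
  that every split carries resolvable signal at the simulated lengths.
* **The LBA mixture** is a two-class model whose classes put identical
  mass on each Dayhoff group but prefer disjoint residues inside every
  group.  Saturated branches then converge within a class's preferred
  residues — misleading site-homogeneous models — while the group-level
  (recoded) data are compositionally homogeneous and a mixture can learn
  the per-site restriction.  The Felsenstein-zone settings used in the
  acceptance checks (pendant long branches 1.5, short branches and
  internal edge 0.12, 1,500 sites) were fixed by a pilot calibration and
  then frozen.

What passing tests show — and do not.  The generator reproduces the
*statistical structure* the analysis assumes (site-profile heterogeneity,
rate variation, missingness, isolated paralogy, compositional bias), not
real EST data: there are no alignment errors, no indels, no model
misspecification beyond the deliberate violations, and dropout is
independent across genes.  Clean-recovery and screen results therefore
demonstrate internal correctness and the qualitative phenomena (LBA, model
ordering), not field performance on real transcriptome data.

## Problem sizes

The shipped checks run on one CPU at desk scale: engine exactness on 4-5
taxon toy-alphabet cases; clean recovery on 12 taxa x 20 genes (~6,000
columns, LG+G4, 30-40 bootstrap replicates); the screen on 8 taxa x 16-20
genes of ~2,000 columns; LBA on 11-13 replicates of 1,500 sites; CV on 10
taxa x 3,000 sites with 5 replicates and 5-class mixtures; the study-shaped
generator at its full 46 x 129 default.  These sizes are the package's own
choice of desk-scale configurations; the full-size analysis (30,270
columns, 100 bootstrap replicates, 10 CV replicates, Dirichlet-process
mixtures) is a cluster-scale exercise outside this package's scope.

## Known limitations

* Finite-mixture CAT with plug-in empirical-Bayes MCMC is a documented
  approximation of the Dirichlet-process original; posterior probabilities
  and CV magnitudes are qualitative analogues.
* The profile M-step uses observed counts, not ancestral expectations;
  profile estimates are slightly blurred at low taxon counts.
* NNI-only search can stop at local optima on hard topologies; bootstrap
  supports inherit this.
* No codon/nucleotide models, no among-partition rate heterogeneity, no
  indel or assembly-error simulation.
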