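# streptophylo

A desk-scale phylogenomics pipeline for the kind of multi-gene protein
analysis used to ask which streptophyte algae are the closest living
relatives of land plants: assemble a supermatrix from per-gene alignments,
screen genes for paralogy against a reference topology, infer trees under
site-homogeneous and site-heterogeneous substitution models, attach
bootstrap and Bayesian support, compare models by cross-validation, and
diagnose compositional bias.  A seed-controlled synthetic-data generator
reproduces the statistical structure of such EST-derived datasets
(~46 taxa x ~129 genes, ~30% missing cells, a fast-evolving clade,
compositionally shifted taxa, occasional paralogous gene copies) so the
whole pipeline can be exercised and validated on one CPU.

It is aimed at people who want a transparent, fully testable
reimplementation of this workflow — for teaching, for method probing
(e.g. long-branch attraction experiments), or as a reference
implementation — not as a replacement for cluster-scale tools.

## The models

Sequence evolution is a reversible continuous-time Markov chain on the 20
amino acids.  A model couples a symmetric exchangeability matrix
`e`, one or more stationary frequency profiles `π_c` with weights `w_c`,
and discrete-gamma rate variation (Γ4: four equal-probability categories,
mean rate 1, shape α).  Per class, `Q_ij = e_ij π_j` rescaled to one
expected substitution per site.  The named families are Poisson, LG+F
(bundled empirical exchangeabilities), GTR (exchangeabilities estimated by
an expected-counts EM), and finite-mixture CAT / CAT-GTR (several
frequency profiles fitted by EM over site-class posteriors — the
site-heterogeneous models that protect against long-branch artifacts).
The site likelihood is

```
L_s = Σ_c w_c (1/4) Σ_g  Σ_states  (Felsenstein pruning under Q_c at rate r_g)
```

computed with per-node rescaling and cached directional messages, so
branch-length optimization and NNI rearrangement scoring are
one-dimensional problems.

The modelling surface follows the statsmodels convention: build a
`TreeLikelihood` model from (alignment, tree, substitution model), call
`.fit()`, and read estimates, per-site log-likelihoods and `summary()`
from the returned results object.

## Worked example

Simulate a small study-shaped dataset, assemble the supermatrix, fit
LG+Γ4, and attach bootstrap supports:

```python
from streptophylo import (make_study_like_dataset, concatenate, TreeLikelihood,
                          nj_start_tree, bootstrap, make_model,
                          majority_consensus, rf_distance)
from streptophylo.supermatrix import filter_gene_occupancy, missing_fraction

ds = make_study_like_dataset(n_taxa=10, n_genes=10, target_missing=0.2,
                             gene_length_median=300, paralog_fraction=0.0,
                             min_branch_length=0.03, seed=11)
kept, occ = filter_gene_occupancy(ds.genes, sorted(ds.tree.taxa), max_missing=3)
sm = concatenate(kept, sorted(ds.tree.taxa))
print(f"supermatrix: {sm.n_taxa} taxa x {sm.n_columns} columns, "
      f"missing fraction {missing_fraction(sm):.3f}, "
      f"{len(kept)}/{len(ds.genes)} genes kept")

aln = sm.to_alignment()
model = make_model("lg", alpha=0.8)
tl = TreeLikelihood(aln, nj_start_tree(aln, model), "lg")
res = tl.fit(max_rounds=3, outer_rounds=1)
print(res.summary())

boot = bootstrap(aln, res.submodel, replicates=20, seed=1)
cons = majority_consensus(boot.sample)
print("consensus RF to generating topology:", rf_distance(cons, ds.tree))
print("bootstrap supports:", sorted(round(v, 1) for v in boot.supports.values()))
```

prints

```
supermatrix: 10 taxa x 3091 columns, missing fraction 0.218, 10/10 genes kept
Tree likelihood fit
=======================================================
model family:        lg
alphabet:            amino20 (K=20)
mixture classes:     1
gamma categories:    4
gamma shape (alpha): 1.1237
taxa / sites:        10 / 3091
unique patterns:     2522
log-likelihood:      -36783.4863
tree length:         3.6689
monotone fit trace:  -36920.29 -> -36787.44 -> -36783.49
consensus RF to generating topology: 0
bootstrap supports: [100.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]
```

The supermatrix realizes the requested ~20% missing cells; the fitted Γ
shape (1.12) and branch lengths maximize the LG+Γ4 likelihood (the trace
is monotone across optimization passes); the bootstrap consensus matches
the generating topology exactly (Robinson–Foulds distance 0) with every
internal edge at 100% support.

The same stages are available from the shell:

```
streptophylo simulate --preset study-like --taxa 12 --genes 20 --seed 1 --out data/
streptophylo concat data/g*.fasta --max-missing 4 --out run/sm
streptophylo screen data/g*.fasta --reference data/true_tree.nwk --out run/screen
streptophylo ml run/sm.phy --model gtr --out run/ml.nwk
streptophylo cv run/sm.phy --models gtr,cat --tree run/ml.nwk --out run/cv.tsv
streptophylo run config.yaml          # whole pipeline from a YAML config
```

See `docs/methods.md` for the models, estimation details, the generator's
assumptions and known limitations.

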