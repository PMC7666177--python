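# pseudotree

Disease pseudotime and progression branches from bulk brain transcriptomes,
via reverse-graph-embedding principal trees.

## The problem

Neurodegenerative diseases such as late-onset Alzheimer's disease progress
over decades, but postmortem cohorts only provide one cross-sectional
transcriptome per donor. `pseudotree` orders such samples along an inferred
molecular trajectory: it learns a low-dimensional principal tree from a
gene-by-sample expression matrix, stages every sample by its geodesic
distance from a root on that tree ("disease pseudotime", scaled to [0, 1]),
and partitions samples into tree branches that act as candidate disease
subtypes. Downstream statistics quantify how the inferred stage relates to
diagnosis, ordinal neuropathology scores, genetic risk-gene expression,
cell-type marker programs, branch-specific expression, and a
"disease-resistant" subgroup of late-stage controls.

The package is aimed at computational biologists analysing bulk (or
single-cell) RNA-seq case/control cohorts, and ships a fully ground-truthed
synthetic-cohort generator so every stage of the pipeline can be tested for
recovery of known structure.

## The model

The core learner minimises the reverse-graph-embedding (DDRTree) objective
over samples x_i ∈ R^G:

    J = Σ_i ‖x_i − W z_i‖²
      + (λ/2) Σ_{k,k'} b_{kk'} ‖W y_k − W y_{k'}‖²
      + γ [ Σ_{i,k} r_{ik} ‖z_i − y_k‖² + σ r_{ik} log r_{ik} ]

subject to **B** = (b_{kk'}) being a spanning tree over the K latent
centers y_k, WᵀW = I, and each soft-assignment row r_i on the simplex.
Each block (R, B, Y, Z, W) has an exact minimiser — softmax assignment,
minimum spanning tree, a linear solve, a convex combination, and an
orthogonal Procrustes step — so alternating minimisation descends
monotonically. Pseudotime is the geodesic distance from a root picked on
the tree's maximum-diameter path (controls-early orientation); branches
are the maximal degree-2 paths of the tree.

Downstream: logistic and proportional-odds ordinal regression of outcomes
on pseudotime, Spearman correlation-shift tests for gene sets, df-3
smoothing-spline cell-type trajectories, one-way ANOVA with Tukey HSD
branch contrasts (studentized-range p-values, BH-adjusted), one-sided
Fisher-exact gene-set enrichment, branch-mean biclustering, and the
top-quintile resistant-control analysis.

## Worked example

```sh
python examples/02_fit_and_stage.py
```

```
DE filter kept 669/2000 genes
converged in 29 sweeps; objective 269144 -> 247881
principal tree: 35 centers, 3 branches, root vertex 22
|Spearman| vs true stage: 0.981  (1 = perfect ordering)
adjusted Rand index vs true arms: 1.000  (1 = exact branch recovery)
```

A synthetic Y-shaped cohort (300 samples, 2000 genes) is filtered to
case/control-differential genes, embedded, and staged. The inferred
pseudotime rank-correlates 0.98 with the latent ground truth and the
branch partition exactly recovers the three arms. Continuing with
`examples/03_staging_associations.py`:

```
case/control ~ pseudotime: coef 4.21 (se 0.51), p = 3.10e-16
ordinal score ~ pseudotime: beta 1.57, LR p = 3.75e-06
GWAS-set correlation shift: +0.50 over background, p = 3.19e-09
          neuron: slope -0.91, p = 0.0e+00 (declines with disease stage)
       microglia: slope +0.80, p = 0.0e+00 (rises with disease stage)
```

Cases concentrate at late pseudotime, the ordinal severity score rises
with stage, the designated risk-gene set is more positively correlated
with stage than background genes, and the planted neuronal-loss /
gliosis programs are recovered with the correct slope signs.
`examples/04_branches_and_resistance.py` closes the loop on the resistant
subgroup: controls in the top pseudotime quintile re-discover the planted
upregulated cluster (overlap 27/50, odds ratio 45, p = 1.7e-27).

There is also a thin CLI mirroring the pipeline stages:

```sh
pseudotree simulate --output-dir out --seed 1
pseudotree all --output-dir out --seed 1
```

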