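# Methods

## Model and optimization

`pseudotree` learns a principal tree by reverse graph embedding: jointly,
a 2-D latent coordinate z_i per sample, K cluster centers y_k constrained
to lie on a spanning tree, a soft assignment matrix R, and an orthonormal
inverse map W from latent to gene space, minimising

J = Σ_i ‖x_i − W z_i‖² + (λ/2) Σ_{k,k'} b_{kk'}‖W y_k − W y_{k'}‖²
  + γ[Σ_{i,k} r_{ik}‖z_i − y_k‖² + σ r_{ik} log r_{ik}],

with B a spanning tree, WᵀW = I, rows of R on the simplex, and the
convention 0·log 0 = 0. Expression is gene-centered before fitting
(the objective is translation-sensitive); no gene scaling is applied.

Every block update is the exact minimiser of J in that block:

- **R**: row-wise softmax of −‖z_i − y_k‖²/σ (max-shifted for overflow
  safety) — the closed-form optimum of the entropy-regularised assignment.
- **B**: the minimum spanning tree of the complete graph on centers under
  squared Euclidean weights (Kruskal; ties broken by lexicographic edge
  index so the result is deterministic).
- **Y**: the linear solve Y(λL + γΓ) = γZR with L the tree Laplacian and
  Γ = diag(Rᵀ1); the system is symmetric positive definite whenever γ > 0
  and at least one assignment row is positive.
- **Z**: the convex combination (WᵀX + γYRᵀ)/(1 + γ).
- **W**: orthogonal Procrustes on XZᵀ (thin SVD UΣVᵀ → W = UVᵀ).
  A rank-deficient XZᵀ is completed with seeded orthonormal columns.
  This Stiefel-constrained step is an exact block minimiser; the other
  objective terms are W-invariant because WᵀW = I.

Sweeps run in the fixed order (R, B, Y, Z, W) and stop when the relative
objective change falls below `tol` (default 1e-5) or after `max_iter`
(default 100) sweeps. Because every step is exact, the objective trace is
non-increasing; the test suite asserts this per block and per sweep.

**Initialization.** W/Z come from the top-2 principal subspace of the
centered matrix; the sign of each latent row of Z is fixed so that its
largest-magnitude entry is positive, which makes the initialization (and
hence the whole deterministic fit) invariant to orthogonal rotations of
the gene space. Y starts from seeded k-means on the latent coordinates; R
and B follow by their exact updates.

## Hyperparameters

| parameter | default | meaning |
|---|---|---|
| d | 2 | latent dimension (the embedding is planar) |
| K | min(N, ⌈2√N⌉) | number of tree centers |
| λ | N/5 | tree-smoothness weight |
| γ | 10 | clustering weight |
| σ | 1e-3 | soft-assignment entropy bandwidth |
| tol | 1e-5 | relative objective tolerance |

K ≈ 2√N keeps the center tree coarse enough that its degree-≠2
decomposition yields a handful of interpretable branches rather than one
branch per noise wiggle. The tree-smoothness default λ = N/5 was chosen
after observing that much larger values (e.g. 5N, the convention of some
reference implementations) contract the center tree deep inside the data
cloud: with the tree shorter than the sample spread, a quarter of the
samples can project onto a single leaf vertex, pseudotime degenerates
into a few atoms, and any quantile-based downstream rule (such as the
top-quintile resistant-control definition) becomes meaningless. At λ =
N/5 the tree spans the cohort, staging is effectively continuous (largest
pseudotime tie ≈ 4% of samples), and recovery of a known latent ordering
improves from ρ ≈ 0.87 to ρ ≈ 0.99 on default synthetic cohorts. All
four parameters are exposed.

## Staging

The fitted tree is realised geometrically with Euclidean edge lengths
(lengths, not squared lengths — a geodesic is a length). Samples project
to their closest point on any edge (clamped segment projection, ties to
the lowest edge id; a centers-only mode is available for comparison).
The root is one end of the maximum-diameter leaf-to-leaf path; with
binary orientation labels the endpoint whose nearby samples have the
lower case fraction is chosen (controls early), otherwise the smaller
vertex index, and an explicit override is available. Pseudotime is the
geodesic distance from the root to the projected point, min-max scaled to
[0, 1] per fit (per cohort). Branches are maximal degree-2 paths,
numbered by their smallest vertex index; samples inherit the branch of
their projected edge. Leave-one-out stability refits the model N times
with one sample dropped and reports the absolute Pearson correlation of
pseudotimes over shared samples; because the min-max anchors (the
outermost centers) move slightly between refits, correlations of ~0.999
rather than exactly 1 are expected even for duplicated samples.

## Association statistics

- **Binary logistic** (diagnosis ~ pseudotime): Newton MLE with a Wald
  z-test; complete or quasi-complete separation (non-finite or diverging
  coefficients) raises an explicit error.
- **Ordinal proportional-odds** (severity score or allele dosage ~
  pseudotime): P(Y ≤ j) = expit(θ_j − βx) with ordered cutpoints; the
  default test is the likelihood ratio against the cutpoints-only null
  (closed-form multinomial log-likelihood when no covariates are
  present); a Wald test is available. Unobserved intermediate levels are
  collapsed with a warning.
- **Correlation shift**: per-gene Spearman correlation with pseudotime
  (average ranks at ties), then a two-group linear model (equivalently a
  pooled t-test) of correlation on set membership against the background
  of all other analysed genes.
- **Cell-type trajectories**: per marker gene, a natural cubic smoothing
  spline whose penalty is tuned by bisection until the trace of the
  smoother matrix equals the target effective degrees of freedom
  (default 3, matched to |trace − df| < 1e-3; ties in pseudotime are
  handled by multiplicity weights). Fitted curves are min-max normalised
  to [0, 1] (constant fits, detected with a numerical tolerance, map to
  0.5), normalised curves are averaged within each marker set
  (normalise-then-average; average-then-normalise is a flag), and an OLS
  slope of the per-sample averaged values on pseudotime is reported with
  its p-value.

## Branch analysis

One-way ANOVA across branches per gene, then Tukey HSD contrasts of every
branch against the reference branch (highest control fraction; ties to
the larger branch, then the smaller id): q = |m_b − m_ref| /
√(MSE/2·(1/n_b + 1/n_ref)) referred to the studentized range with
(number of branches, N − branches) parameters. The studentized-range
survival function is computed by fixed-grid Gauss–Legendre integration of
the classical double integral (64 nodes over the scaled-chi outer
variable, 128 over the normal inner variable), vectorised over genes;
agreement with an independent oracle implementation is ~1e-13 absolute,
and for two groups it reproduces the pooled two-sample t-test to 1e-8.
Single Tukey contrasts are family-adjusted by construction, so their
stand-alone type-I error is below nominal; the exactly-calibrated event
(used in the calibration tests) is "any pairwise contrast rejects",
i.e. the range statistic exceeding its critical value. BH adjustment is
applied across genes within each branch contrast (a global-BH flag
exists). Genes with zero within-branch variance receive the degenerate p
(0 if the means differ, 1 otherwise) and a flag.

Fisher enrichment uses the one-sided (greater) hypergeometric tail over
the analysed-gene universe, sample odds ratio ad/bc with a 0.5 continuity
correction only when a cell is zero, BH across sets. Branch signatures
z-score each gene across samples (min-max optional; constant genes become
zero rows and are flagged) and average within branch; biclustering is
agglomerative hierarchical clustering (complete linkage, Euclidean) on
both axes with the row dendrogram cut into a configurable number of gene
clusters (default 6). Resistant individuals are controls strictly above
the type-7 empirical 0.8-quantile of all pseudotimes; the resistant-vs-
rest differential expression runs genome-wide (all measured genes, not
just the manifold subset), and its direction-split gene lists are tested
for overlap against bicluster gene sets (and, in tests, against the
planted cluster) with one-sided Fisher tests plus UpSet-style exclusive
intersection counts.

## Synthetic cohorts

The generator emulates the structure the analysis assumes about bulk
brain RNA-seq case/control cohorts, with full ground truth:

- **Latent tree**: `path`, `y`, or `double_y` topologies with straight
  arms (default arm length 5, 5 vertices per arm); samples placed
  uniformly by arc length (per-branch weights configurable). True
  pseudotime is the geodesic distance from the root, min-max scaled so 0
  and 1 are attained exactly; true branches come from the degree-≠2
  decomposition.
- **Expression** (default `linear_gaussian`): X = s·W_true Z + F + ε with
  column-orthonormal W_true (s = 10), ε ~ N(0, 1), and F the planted
  program matrix — logistic-in-pseudotime curves (amplitude ~2, random
  centers 0.25–0.75, widths 0.08–0.15) for increasing/decreasing genes,
  on-branch-only shifts for branch-specific genes. W_true rows are zero
  for flat genes, so flat genes are exact nulls. Defaults: 300 samples,
  2000 genes, 15% increasing, 15% decreasing, 10% branch-specific.
  A negative-binomial counts mode (per-gene rate exp(β0 + F) times a
  log-normal library size, dispersion 10) produces integer counts plus
  log2(CPM+1) values for the counts-based entry point.
- **Labels**: P(case) = expit(−2 + 4t); a 4-level ordinal score from the
  proportional-odds model with cutpoints (−1, 0.5, 2) and slope 2;
  dosage ~ Binomial(2, expit(−1.5 + 1.5t)).
- **Resistance**: 9 controls (or as many as the label draw produced)
  above the 0.8 true-pseudotime quantile get +2 (log scale) on a
  designated 50-gene cluster drawn from the flat genes.
- Marker sets (neuron = decreasing; microglia/astrocyte/oligodendrocyte
  = increasing) and a 60-gene "GWAS" set (increasing) are designated
  among the program genes.

One master seed drives a named substream per operation, so any stage can
be regenerated independently and all outputs are bit-reproducible.

**What the generator does not emulate**: GC/length biases and their
normalisation, batch structure beyond a single additive shift, realistic
gene-gene correlation beyond the planted low-rank-plus-programs
structure, dropout, or genotype structure beyond a scalar dosage.
Passing recovery tests therefore demonstrate correctness of the
algorithms under the stated generative assumptions, not performance on
real cohorts.

## Numerical and design choices

- BH step-up is the multiple-testing procedure wherever an FDR is
  mentioned; the DE gene filter defaults to FDR 0.10 with the threshold
  exposed (an FDR 0.05 convention also exists in the literature for this
  filter; both are one parameter away).
- The case/control gene filter is an unmoderated per-gene two-group
  linear-model t-test on log-scale values — a deliberate simplification
  appropriate for synthetic data without count-depth artifacts; the
  high-variance filter is the sensitivity alternative.
- Covariate adjustment replaces each gene by its OLS residual plus the
  gene mean; rank-deficient designs are rejected with the collinear
  columns named.
- The resistant-quantile uses the type-7 (linear interpolation)
  convention, with strict exceedance, documented because "top quintile"
  is ambiguous at ties.
- Problem sizes in the test and acceptance suites (cohorts of 200–300
  samples, 500–2000 genes, 10 seeds per recovery check, 1000 null
  replicates per calibration check) are chosen to give Monte-Carlo
  standard errors comfortably inside the asserted bands on a single CPU.

## Known limitations

- The learned tree is sensitive to K and λ in the regime where the
  latent signal is weak; defaults target cohorts of a few hundred
  samples.
- Pseudotime carries no uncertainty estimate; leave-one-out correlation
  is the only stability measure provided.
- The ordinal model assumes proportional odds; violations are not tested
  for.
- Branch ANOVA is unadjusted for within-branch covariates.
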