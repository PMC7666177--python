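"""Associate inferred pseudotime with outcomes and cell-type programs.

Logistic regression for case/control status, proportional-odds ordinal
regression for the severity score, a Spearman correlation-shift test for
the designated GWAS gene set, and df-3 smoothing-spline trajectories of
cell-type marker sets.
"""

import numpy as np

import pseudotree as pt

cohort, truth = pt.simulate_cohort(topology="y", n_samples=300, n_genes=2000, seed=1)
case = (cohort.metadata["diagnosis"] == "case").to_numpy()
expr = cohort.expression_matrix()
sel = pt.de_gene_selection(expr, case)
sub = expr.subset_genes(sel.kept_gene_ids)
model = pt.fit(sub.values, pt.DDRTreeParams(seed=1))
_, staging = pt.stage_samples(model, orientation_labels=case.astype(float))
t = staging.pseudotime

res = pt.logistic_assoc(t, case.astype(float))
print(f"case/control ~ pseudotime: coef {res.coef:.2f} (se {res.se:.2f}), p = {res.p:.2e}")
ords = pt.ordinal_assoc(t, cohort.metadata["score"].to_numpy())
print(f"ordinal score ~ pseudotime: beta {ords.coef:.2f}, LR p = {ords.p:.2e}")
dos = pt.ordinal_assoc(t, cohort.metadata["dosage"].to_numpy())
print(f"allele dosage ~ pseudotime: beta {dos.coef:.2f}, LR p = {dos.p:.2e}")

gwas = [g for g in cohort.gwas_set if g in set(sub.gene_ids)]
_, shift, p = pt.geneset_correlation_shift(sub, t, gwas)
print(f"GWAS-set correlation shift: +{shift:.2f} over background, p = {p:.2e}")

markers = {k: [g for g in v if g in set(sub.gene_ids)] for k, v in cohort.marker_sets.items()}
for name, traj in pt.celltype_trajectory(sub, t, markers).items():
    print(f"{name:>16}: slope {traj.slope:+.2f}, p = {traj.slope_p:.1e} "
          f"({'declines' if traj.slope < 0 else 'rises'} with disease stage)")
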