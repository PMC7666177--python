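"""Generate a synthetic branching cohort and inspect its ground truth.

The generator places samples on a latent Y-shaped tree, drives expression
from the latent position (plus planted monotone / branch-specific gene
programs), and draws diagnosis, an ordinal severity score and an allele
dosage that are stochastically monotone in latent stage.
"""

import numpy as np

import pseudotree as pt

cohort, truth = pt.simulate_cohort(topology="y", n_samples=300, n_genes=2000, seed=1)

print(f"expression: {len(cohort.gene_ids)} genes x {len(cohort.sample_ids)} samples")
print(f"case fraction: {(cohort.metadata['diagnosis'] == 'case').mean():.2f}")
print(f"true branches: {sorted(set(truth.true_branch))}")
programs = {}
for p in truth.gene_programs.values():
    key = p.split("(")[0]
    programs[key] = programs.get(key, 0) + 1
print(f"gene programs: {programs}")
print(f"resistant controls planted: {len(truth.resistant_samples)}")
print(f"true pseudotime range: [{truth.true_pseudotime.min():.0f}, "
      f"{truth.true_pseudotime.max():.0f}] "
      f"(mean {truth.true_pseudotime.mean():.2f})")
# cases should sit later on the trajectory than controls by construction
case = (cohort.metadata["diagnosis"] == "case").to_numpy()
print(f"mean true stage, cases vs controls: "
      f"{truth.true_pseudotime[case].mean():.2f} vs {truth.true_pseudotime[~case].mean():.2f}")
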