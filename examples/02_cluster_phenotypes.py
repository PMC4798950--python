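"""Discover phenotypes by set-based clustering with a data-splitting cutoff.

Four well-separated phenotypes are planted, three experiments each; the
intermingling score (chance-level 1-NN accuracy -> 1, perfect separability
-> 0) drives greedy merging, and the cutoff calibrated from within-experiment
splits prunes the tree into phenotype clusters.
"""

import numpy as np

from phenolearn import assign_phenotypes, build_cluster_tree, determine_cutoff
from phenolearn.phenoclust import intermingling_score

rng = np.random.default_rng(0)
means = rng.normal(0, 8.0, (4, 3))
observations = {
    (p, r): means[p] + rng.normal(0, 1, (40, 3))
    for p in range(4)
    for r in range(3)
}

a, b = observations[(0, 0)], observations[(0, 1)]
print("same-phenotype intermingling score:",
      round(intermingling_score(a, b, seed=0), 3), "(1 = indistinguishable)")
print("cross-phenotype intermingling score:",
      round(intermingling_score(a, observations[(1, 0)], seed=0), 3))

cutoff = determine_cutoff(observations, seed=1)
root = build_cluster_tree(observations, seed=2)
assignment = assign_phenotypes(root, cutoff)
print(f"\ncutoff score: {cutoff:.3f}")
print(f"phenotypes found: {assignment.n_phenotypes} (4 were planted)")
for (p, r), label in sorted(assignment.labels.items()):
    print(f"  experiment (planted {p}, rep {r}) -> phenotype {label}")
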