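"""Categorical dissimilarities and hierarchical clustering on synthetic data.

Generates a 116 x 22 nominal matrix with 3 planted groups, compares the five
dissimilarity measures, and cuts an average-linkage dendrogram at k = 3.
"""

import numpy as np

from nomtrait import (
    MEASURES,
    Partition,
    SyntheticSpec,
    adjusted_rand,
    cut_tree,
    dissimilarity,
    generate,
    hierarchical_cluster,
)

tm, truth = generate(SyntheticSpec(theta=0.9, seed=7))
pt = Partition(tm.species_ids, truth)
print(f"matrix: {tm.n} species x {tm.m} traits, 3 planted groups (theta=0.9)")

for measure in MEASURES:
    d = dissimilarity(tm, measure)
    dg = hierarchical_cluster(d, "average")
    part = cut_tree(dg, 3)
    ari = adjusted_rand(part, pt)
    off = d.values[np.triu_indices(tm.n, 1)]
    print(f"{measure:8s} mean dissimilarity {off.mean():.3f}   "
          f"ARI vs planted groups at k=3: {ari:.3f}")
# ARI = 1 means the cut reproduces the planted partition exactly
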