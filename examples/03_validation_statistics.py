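"""The significance machinery on small worked inputs.

Shows the Jensen-Shannon CMN similarity, the edge-overlap hypergeometric
test, the observed-proportion (OP) TF-enrichment permutation test and
Benjamini-Hochberg correction.
"""

import numpy as np

from cmnet.cmn import cmn_similarity
from cmnet.io import GenomicInterval, Interaction
from cmnet.validation import (
    bh_correct,
    hypergeom_overlap,
    network_overlap_pvalue,
    tf_enrichment_test,
)

# --- CMN similarity: 1 - Jensen-Shannon divergence (base-2 logs)
p = np.array([0.5, 0.5])
q = np.array([1.0, 0.0])
print(f"sim((0.5,0.5),(1,0)) = {cmn_similarity(p, q):.5f}  (1 = identical, 0 = disjoint)")

# --- edge overlap of two networks vs the hypergeometric null
net_a = {frozenset(e) for e in [("GATA1", "LDB1"), ("LDB1", "LMO2"), ("GATA1", "TAL1")]}
net_b = {frozenset(e) for e in [("GATA1", "LDB1"), ("LDB1", "LMO2"), ("LMO2", "TAL1")]}
print(f"edge-overlap p = {network_overlap_pvalue(net_a, net_b):.4f} "
      "(prob. of >= 2 shared edges among all node-pair edges)")

# --- generic set overlap (e.g. predicted co-factors vs a proteomics list)
universe = {f"P{i}" for i in range(40)}
annotated = {f"P{i}" for i in range(12)}
predicted = {f"P{i}" for i in range(8)} | {"P30", "P31"}
print(f"set-overlap p = {hypergeom_overlap(predicted, annotated, universe):.2e}")

# --- OP test: do claimed interactions truly contain a TF's ChIP-seq signal?
interactions = [
    Interaction(f"I{j}", GenomicInterval("chr1", j * 100_000, j * 100_000 + 400),
                GenomicInterval("chr1", j * 100_000 + 50_000, j * 100_000 + 50_400))
    for j in range(100)
]
claimed = {f"I{j}" for j in range(15)}
signal = [GenomicInterval("chr1", it.anchor_a.center, it.anchor_a.center + 50)
          for it in interactions[:15]]
result = tf_enrichment_test(claimed, signal, interactions, n_perm=500, seed=0)
print(f"OP = {result.observed:.2f}, permutation p = {result.pvalue:.4f} "
      "(signal present only in the claimed set)")

# --- multiple testing
print("BH-corrected [0.01, 0.02, 0.03] ->", [round(x, 3) for x in bh_correct([0.01, 0.02, 0.03])])
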