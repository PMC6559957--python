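"""Sample clustering and k-means temporal patterns.

Hierarchical clustering (complete linkage, Euclidean on log2(FPKM+1))
groups replicate libraries; k-means on z-standardized stage profiles
groups features into trend clusters labelled increasing / decreasing /
fluctuating / stable.
"""

from folliscan import GeneratorConfig, generate_bundle
from folliscan.expression import (
    ExpressionTable,
    hierarchical_cluster_samples,
    kmeans_patterns,
)

bundle = generate_bundle(GeneratorConfig(seed=1))
lnc = bundle.truth[
    bundle.truth.planted_role.isin(["lncRNA", "known_lncRNA"])
    & (bundle.truth.planted_pattern != "stable")
]
tab = ExpressionTable(
    bundle.expression.values.loc[list(lnc.transcript_id)], bundle.design
)

dendro = hierarchical_cluster_samples(tab)
a, b = dendro.root_split()
print("root split of the sample dendrogram:")
print(" ", sorted(a))
print(" ", sorted(b))
clades = dendro.stage_clades(bundle.design)
print(f"replicates form stage clades: {clades}")

all_lnc = bundle.truth[bundle.truth.planted_role.isin(["lncRNA", "known_lncRNA"])]
tab_all = ExpressionTable(
    bundle.expression.values.loc[list(all_lnc.transcript_id)], bundle.design
)
cl = kmeans_patterns(tab_all, k=4, seed=1)
print("\nk-means clusters (k=4) and their trend groups:")
for cid, size in cl.cluster_sizes().items():
    print(f"  cluster {cid}: {size} lncRNAs, {cl.pattern_groups[cid]}")
# The root split separates the fetal stages (E65-E105) from the
# late-fetal/postnatal ones (E135, D7, D30), and each planted archetype
# lands in its own cluster.
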