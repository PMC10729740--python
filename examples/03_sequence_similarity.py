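"""Score clonotypes by sequence similarity to two TCR clusters.

The diffusion-map pseudotime similarity metric: positive scores mean a
clonotype's TCR sequence is closer to the effector cluster (0), negative
closer to the naive cluster (3).  Binned association then tests whether
sequence similarity to the effector cluster tracks the cytotoxic
transcriptional program — the package's analogue of relating sequence
similarity to phenotype.
"""

import pandas as pd

import clonoscope as cs

cohort = cs.simulate_cohort(cs.CohortConfig(seed=0))
distances = cs.compute_tcrdist(cohort.clonotypes)
graph = cs.build_graph(distances)
space = cs.diffusion_components(graph, n_dcs=15)

truth = pd.Series(cohort.truth.true_cluster).loc[distances.ids]
clusters = cs.ClusterAssignment(labels=truth, resolution=0.0)

similarity = cs.pairwise_cluster_similarity(space, clusters, 0, 3)
own = similarity.scores[clusters.labels == 0]
print(f"effector-cluster members with positive similarity: {(own > 0).mean():.0%}")

norm = cs.normalize_log_cpm(cohort.cells)
var = cohort.cells.var
cytotoxic = cs.score_signature(norm, list(var.index[var["program"] == "cytotoxic"]))
per_clonotype = cytotoxic.groupby(norm.obs["clonotype_id"], observed=True).mean()

r, p, bins = cs.binned_association(similarity, per_clonotype, n_bins=25)
print(f"binned association, similarity vs cytotoxic signature: "
      f"r = {r:.2f}, p = {p:.2g} over {len(bins)} nonempty bins")

edges = cs.cluster_connectivity(space, clusters, k=20)
print("\ncluster-pair connectivity (observed/expected inter-cluster edges, clipped):")
print(edges[["cluster_a", "cluster_b", "weight"]].round(2).to_string(index=False))
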