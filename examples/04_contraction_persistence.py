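"""Track clonotype frequencies across timepoints and model contraction.

Computes per-cluster contraction strength (log10 difference of mean
repertoire share, convalescent vs acute), fits the TRAV-usage linear model of
contraction, and predicts contraction from a reference set of contracting
clonotypes via alpha-chain sequence neighborhoods.
"""

import numpy as np
import pandas as pd

import clonoscope as cs

cohort = cs.simulate_cohort(cs.CohortConfig(seed=0))
labels = pd.Series(cohort.truth.true_cluster)

freq = cs.clonotype_frequencies(cohort.cells.obs, totals=cohort.totals)
table = cs.contraction_strength(freq, labels)
print("per-cluster contraction (negative = contraction):")
cols = ["cluster", "mean_acute_pct", "mean_convalescent_pct", "contraction_strength", "p"]
print(table.per_cluster[cols].round(3).to_string(index=False))

# TRAV regression on a 12-cluster cohort with a planted usage-contraction slope
recs, trav_labels, contraction = cs.planted_trav_cohort(
    n_clusters=12, slope=-0.01, intercept=-0.2, noise_sd=0.05, seed=0
)
usage = cs.trav_usage(recs, trav_labels)
model = cs.fit_trav_model(usage, contraction)
print(f"\nTRAV model: planted slope -0.010, "
      f"fitted {model.coefficients['TRAV1-S']:.4f}, intercept {model.intercept:.3f}")

# reference-based prediction: most-contracting cluster's clonotypes as reference
reference = [r for r in cohort.clonotypes if labels[r.clonotype_id] == 0]
pred = cs.predict_contraction_from_reference(cohort.clonotypes, reference)
per_cluster = pred.groupby(labels.loc[pred.index].values).mean()
print("\nmean predicted contraction per cluster "
      "(cluster 0 is the reference-like, most contracting):")
print(per_cluster.round(2).to_string())
print("realized contraction:", np.round(cohort.truth.realized_contraction.values, 2))
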