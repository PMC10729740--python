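"""Generate a synthetic antigen-specific CD8+ T cell cohort.

Builds the default cohort (4 TCR clusters x 25 clonotypes, 12 patients, three
blood draws T1/T2/T3) and prints its shape and the realized per-cluster
contraction, which should sit near the configured targets.
"""

import clonoscope as cs

config = cs.CohortConfig(seed=0)
cohort = cs.simulate_cohort(config)

print(f"clonotypes: {len(cohort.clonotypes)}")
print(f"cells x genes: {cohort.cells.shape}")
print(f"plasma block: {cohort.plasma.shape} (patient-timepoint x protein)")
print(f"HLA block: {cohort.hla.shape} (patient x allele, presence/absence)")
print(f"cDC block: {cohort.cdc.shape} (patient x feature)")
print("\ncluster programs:", cohort.truth.cluster_programs)
print("\ntarget contraction profile:", config.contraction_profile)
print("realized contraction (log10 units; negative = cluster shrinks at T3):")
print(cohort.truth.realized_contraction.round(3).to_string())
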