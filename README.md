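# clonoscope

Tools for asking how much a CD8+ T cell's receptor sequence — versus its
environment — determines what that cell becomes and whether it persists after
infection.

Antigen-specific CD8+ T cells sharing a single peptide-MHC specificity are
surprisingly diverse: clonotypes targeting the same epitope split into
sequence-similar TCR clusters with distinct transcriptional programs (naive,
memory, interferon, cytotoxic) and distinct post-infection fates.  `clonoscope`
implements, as a tested reusable library, the quantitative machinery for
analyzing this structure in longitudinal single-cell multi-omic cohorts:

- **TCR space** — paired-chain TCRdist-style distances
  (`d = Σ_loops w · min(4, 4 − BLOSUM62)` over CDR1/2/2.5 at weight 1 and
  trimmed CDR3α/β at weight 3, central-gap alignment), PCA + kNN graphs,
  Leiden clustering with a resolution search (highest resolution in 0.01
  steps that avoids clusters below a minimum size), and UMAP embeddings.
- **Sequence similarity** — diffusion-map components of the TCR graph;
  pseudotime from root clonotypes; the two-cluster similarity score
  `s(i) = mean_{r∈B} dpt_r(i) − mean_{r∈A} dpt_r(i)` (positive ⇒ closer to A);
  25-bin association of similarity with any per-clonotype variable; PAGA-style
  cluster connectivity (observed / degree-expected inter-cluster edges).
- **Phenotype** — ln(CPM+1) normalization, one-vs-rest Mann–Whitney marker
  genes with Benjamini–Hochberg control, Ward/silhouette co-expression module
  discovery on the top markers, signature scoring, per-batch standardization,
  CITE-seq normalization against background antibodies, and kNN density
  diffusion on embeddings.
- **Persistence** — clonotype repertoire percentages per patient-timepoint;
  cluster contraction strength
  `C = log10(mean %_conv + 1) − log10(mean %_acute + 1)` with Welch tests;
  correlation of contraction with phenotype features; OLS of contraction on
  screened TRAV-gene usage; reference-based contraction prediction from
  α-chain sequence neighborhoods; Kaplan–Meier survival splits with a 2×2 χ².
- **Factor importance** — per-omic 200-100-50-100-200 ReLU autoencoders
  (50 latents at each omic's native unit level), cell-level Pearson tests of
  every latent against every expression PC, observed vs `n·α` expected
  significant-correlation counts, and the equal-importance χ² across omics;
  plus the plasma-protein × transcriptomic-PC intersection analysis.
- **Synthetic cohort** — a first-class generator producing clonotypes with
  cluster-specific V/J usage and CDR3 motifs, cells with program activities
  mixed from TCR-cluster loadings and patient-level environment latents
  (plasma / HLA / dendritic-cell), negative-binomial counts, and per-cluster
  contraction realized against a background CD8 pool — with complete ground
  truth, so every stage of the pipeline is exercisable and falsifiable without
  patient data.

## Worked example

```python
import pandas as pd
import clonoscope as cs

cohort = cs.simulate_cohort(cs.CohortConfig(seed=0))
table = cs.importance_pipeline(cohort, seed=0)
print(table.counts[["omic", "observed", "expected", "observed_minus_expected"]])
```

```
  omic  observed  expected  observed_minus_expected
   tcr       423     125.0                    298.0
plasma       190     117.5                     72.5
   hla       148     105.0                     43.0
   cdc       157     112.5                     44.5
```

Each row counts significant (latent, expression-PC) Pearson correlations for
one factor block against the α-budget expectation `n_pairs × 0.05`.  Here the
generator mixed program activity with weight 0.7 on the TCR cluster and 0.1 on
each environment block, and the readout recovers that: the TCR omic's excess
(+298) dwarfs every environment block — the package's analogue of finding that
receptor sequence, not environment, dominates antigen-specific T cell
phenotype.  Running `python examples/04_contraction_persistence.py` prints the
matching persistence readout:

```
 cluster  mean_acute_pct  mean_convalescent_pct  contraction_strength     p
       0           8.234                  0.000                -0.965 0.000
       1           9.474                  1.141                -0.690 0.000
       2           7.715                  3.431                -0.294 0.000
       3           8.191                  8.210                 0.001 0.985
```

i.e. the effector-program cluster 0 contracts ~10-fold in repertoire share
from acute disease to convalescence while the naive-program cluster 3
persists, matching the generator's contraction profile (−1.0, −0.6, −0.3, 0.0)
in log10 units.  The `examples/` directory holds one short narrative script
per capability.

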