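# Methods

This note documents the models and procedures implemented in `clonoscope`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic cohort does and does not emulate.

## Paired-chain TCR distance

The distance between two clonotypes sums per-position substitution penalties
over six loops per receptor: the germline-encoded CDR1, CDR2 and CDR2.5 of
each chain (weight 1 each) and the CDR3 junctions (weight 3), with the CDR3
trimmed of its 3 N-terminal and 2 C-terminal residues — the conserved anchors
carry little specificity information.  The per-position penalty is
`min(4, 4 − BLOSUM62(a, b))` with 0 for identical residues; unequal-length
loops are aligned by inserting a single central gap block in the shorter
sequence at 4 penalty units per gapped position (times the loop weight).
This is a semimetric: symmetry, non-negativity and identity hold, but the
triangle inequality is not guaranteed and nothing downstream relies on it.

Germline loops for the simulated V gene names are bundled in a minimal
table; records with V genes outside that table fall back to CDR3-only
distances (a warning in `auto` mode, an error in `germline` mode).  Trimming,
gap penalty, loop weights and chain selection are all exposed in
`TcrDistParams`; the α-chain-only parameterization (Vα loops + CDR3α) is the
one used for reference-based contraction prediction.

## TCR graph, clustering, embedding

Rows of the (centered) distance matrix are treated as feature vectors and
reduced by PCA to 50 components; this "distances-to-all as features" reading
is the most direct one for a distance matrix, and a classical-MDS alternative
would differ only by an affine transform of the spectrum.  kNN graphs
(default 30 neighbors in the first 20 PCs, Euclidean) get locally adaptive
Gaussian weights `exp(−d²/(σᵢσⱼ))` with σᵢ the distance to the 7th neighbor
(self-tuning local scale), symmetrized by max.  Identical points receive
weight 1.

Leiden clustering scans resolutions from 0.5 to 2.0 in 0.01 steps and keeps
the partition at the highest resolution at which no cluster falls below
`min_cluster_size = 5` clonotypes.  "Over-clustering" has no formal
definition; a minimum admissible cluster size is a reproducible, tunable
proxy for the judgment a human analyst applies.  The cluster count is
empirically non-decreasing in resolution up to rare single-step dips caused
by Leiden's greedy refinement; the search is robust to these because it
tracks the admissibility of each partition, not the trend.  2-D embeddings
use UMAP on the graph's PC coordinates with a fixed random state; inputs of
fewer than 5 points fall back to the first two PCs (UMAP's optimizer is not
meaningful there).

## Diffusion similarity

The graph kernel is row-normalized into a random-walk transition matrix and
its symmetric conjugate eigendecomposed per connected component (dense; the
clonotype-level matrices are small).  The trivial stationary eigenvector is
dropped and the top 15 nontrivial eigenpairs retained; coordinates are scaled
by λ/(1−λ).  Pseudotime from a root is the Euclidean distance in these
scaled coordinates — a deliberate simplification of full branching
pseudotime: every quantity consumed downstream (cluster-pair scores, binned
associations) depends only on relative orderings, on which the two agree.
Pseudotime across connected components is infinite.

The two-cluster similarity score of clonotype *i* is the mean pseudotime over
roots in cluster B minus the mean over roots in cluster A, so positive values
mean "closer to A".  Roots are clonotypes (the TCR space has no finer unit).
Binned association cuts the score range into 25 equal-width bins, drops empty
bins, and Pearson-correlates per-bin mean score with per-bin mean variable;
per-bin means (rather than geometric centers) on the score axis make the
self-association exactly 1.  Cluster connectivity builds a fresh 20-NN graph
in diffusion coordinates and reports, per cluster pair, observed inter-cluster
edges over the count expected if edges were placed proportionally to cluster
degree sums, clipped to [0, 1].

## Phenotype

Expression is normalized per cell to ln(1 + CPM); zero-total cells are
excluded.  Marker genes use a one-vs-rest two-sided Mann–Whitney U per gene
(exact where SciPy's implementation supports it, hence the exact null on tiny
fixtures), Benjamini–Hochberg adjusted within each label; genes constant
across the compared cells get p = 1.  Co-expression modules: the union of the
top 25 markers per label is correlated gene-by-gene, Ward-clustered on the
distance 1 − r, and the module count chosen from the candidate range by
maximal mean silhouette on that distance (ties to the smallest k; a fully
degenerate geometry falls back to the smallest k with a warning).

Signature scores are means of normalized expression over the present genes of
a set.  Batch correction is deliberately simple: per-batch centering and unit
scaling of each signature column.  Iterative mixture-model integration and
batch-balanced neighbor graphs are published external methods, not this
package's contribution; per-batch standardization removes exactly the
additive/multiplicative batch structure the synthetic generator can inject,
which is what the tests exercise.  Surface proteins are normalized per cell
against background (isotype-like) antibodies: z-scores of ln(1+count) using
the cell's own background mean and SD; cells with zero background SD are
flagged and zeroed.

Embedding density: a Gaussian kernel density of member cells (Scott-rule
bandwidth from the member coordinates, falling back to the global spread for
degenerate member sets), min-max scaled to [0, 1], then diffused five steps
along the transpose of the row-normalized (k+1)-neighbor adjacency with
self-loops.  Propagating along the transpose makes each step mass-conserving
(total density is exactly preserved), which is the invariant the pipeline
relies on; on symmetric regular layouts the row-stochastic and transpose
formulations coincide.

## Persistence

A clonotype's repertoire share is 100 × (its cells) / (all CD8 cells of that
patient-timepoint); the denominator can be supplied externally (the generator
reports a totals table including its background CD8 pool), otherwise the cell
table itself is used.  A clonotype observed anywhere for a patient
contributes explicit zeros at that patient's other timepoints.  Cluster
contraction strength pools T1/T2 as acute, T3 as convalescent:
`C = log10(mean %_conv + 1) − log10(mean %_acute + 1)`, compared by a Welch
t-test on the per-observation percentage vectors.  Note the log10(%+1)
transform bounds attainable contraction: a cluster with mean acute share *m*
cannot contract below −log10(m + 1).

The TRAV model screens each TRAV gene's per-cluster usage percentage by
univariate Pearson p < α against contraction, then fits OLS of contraction on
the kept columns plus an intercept at the cluster level (the level at which
contraction is defined); collinear designs are repaired by dropping columns
in order of worst screen p.  Reference-based prediction counts, for each
study clonotype, reference clonotypes with α-chain distance strictly below
the mean of all within-study pairwise α-chain distances (all ordered pairs
excluding self; duplicated references deliberately increment counts), and
min-max scales the counts to [0, 1].  Survival splits dichotomize a patient
score at a threshold, estimate Kaplan–Meier curves per arm, and test a 1-df
χ² without continuity correction on the 2×2 survival-by-arm table.

## Factor importance

Each factor block enters at its native unit level — TCR features per
clonotype (one-hot V/J usage, CDR3 length and amino-acid composition per
chain), plasma per patient-timepoint, HLA presence/absence and dendritic-cell
features per patient.  Features are standardized (constant features dropped)
and compressed by a fully connected 200-100-50-100-200 ReLU autoencoder
trained with adam for at most 25 epochs (squared error, early stop at
relative loss change < 1e-4), deterministic per seed.  The 50 bottleneck
activations are broadcast to cells through the unit map and Pearson-tested
against each of 50 expression PCs; cell-level testing is the only alignment
that lets clonotype-level and patient-level omics share one phenotype matrix,
and it inflates the effective n identically across omics, preserving the
comparison's symmetry.  Significance is raw two-sided p < 0.05 with no
multiplicity correction because the expectation explicitly budgets for α:
expected = n_valid_pairs × α (latents constant after broadcast are skipped
and the budget adjusted).  The χ² test compares per-omic observed counts to
an equal split (total/4) with df = 3.

**Known limitation.**  The per-omic counts are sums of *correlated*
indicator variables — the 50 latents of one autoencoder are strongly mutually
dependent — so under a global null the counts are overdispersed relative to
the binomial α-budget and the equal-importance χ² is anti-conservative (its
null rejection rate is well above α).  The mean count still sits at the
α-budget expectation, the comparison between omics remains symmetric (each
omic wins the observed−expected ranking in ≈ 25% of pure-noise cohorts), and
effect-driven dominance (w_tcr = 0.7) is recovered essentially always; the χ²
p-value should be read as a descriptive ranking statistic, not a calibrated
test.

The plasma-protein analysis correlates individual proteins with transcriptomic
PCs aggregated to patient-timepoint units, Ward-clusters rows and columns
separately (k by maximal silhouette in 3–10), and scores a chosen
(protein-cluster, PC-cluster) intersection by the mean standardized level of
the significantly correlated proteins (per unit) and the mean of the
reciprocally significant PC columns (per cell).

## Synthetic cohort

The generator is the package's ground-truth instrument.  Defaults: 4 TCR
clusters × 25 clonotypes, 12 patients, three draws (T1/T2 acute, T3
convalescent), ~12 cells per clonotype per draw (~2,700 cells), 300 genes of
which 4 × 25 belong to the naive/memory/interferon/cytotoxic programs, 40
plasma proteins, 12 surface proteins (4 background), 30 dendritic-cell
features, a 30-allele HLA pool.

*Clonotypes.*  Each cluster prefers one V gene per chain (75% usage) and
carries a consensus CDR3 per chain (length 10–18, fixed 3-residue anchors);
members mutate middle positions with probability 0.25 and jitter length by
±1.  Cluster consensus motifs form a mutation chain (each cluster's consensus
derives from the previous one at 35% per-position divergence), so clusters
have close and distant sequence relatives — as observed for real
antigen-specific clusters — and the diffusion space has a usable gradient
rather than four mutually equidistant islands.  Clonotypes are assigned to
patients cyclically: sequence clusters span patients (public specificity
groups), and balanced assignment prevents patient-level factors from becoming
artifactual proxies of cluster composition.

*Phenotype.*  Per-cell program activity mixes the standardized cluster
loading with standardized patient(-timepoint) latents and per-cell noise
using weights (w_tcr, w_plasma, w_hla, w_cdc, w_noise) that sum to 1
(default 0.7/0.1/0.1/0.1/0).  Cluster loadings are one-hot on the cluster's
program except the cytotoxic axis, which is graded by the negated contraction
target — contracting clusters are effector-like, the short-lived-effector
biology the pipeline is meant to recover.  Gene counts are negative binomial
(dispersion 0.5) with log-mean `base + 0.3 × activity` plus optional per-batch
gene shifts and a lognormal library-size factor.  The 0.3 expression effect
gives a realistic signal-to-noise regime for scRNA-seq program signals; with
a near-noiseless effect the binary significance counting in the importance
analysis saturates (any 0.1-weight factor is detectable at n ≈ 3,000 cells)
and the comparison degenerates, while 0.2–0.4 all behave equivalently.

*Environment blocks.*  Plasma is low-rank + noise over patient-timepoint
units with a block-structured loading (each protein block loads on one
program latent — the "inflammatory block ↔ effector program" coupling);
dendritic-cell features likewise at patient level; HLA is Bernoulli
presence/absence whose phenotype-relevant latent is a fixed random projection
of the allele vector.

*Contraction.*  Acute cell counts are Poisson around per-clonotype rates;
T3 rates are scaled by per-cluster multipliers solved by proportional fitting
on expected percentages so the realized log10 contraction matches the target
profile, against a constant per-patient background CD8 pool (30% of the acute
total; reported in the totals table, not instantiated as cells).  Because
repertoire shares renormalize, targets are only reachable down to
−log10(mean acute % + 1); the solver clips below that.  Realized profiles land
within ±0.1 of targets over seeds.

*What the generator does not emulate* — and hence what passing tests do not
show about real data: V(D)J recombination statistics and thymic selection;
UMI/dropout artifacts beyond NB overdispersion; doublets and ambient RNA;
clonotype sharing across patients; time-varying environment effects;
nonlinear TCR-phenotype relationships.  The paper-scale analysis infers
association only; the generator's linear mixing is an assumption for testing
recoverability, not a mechanistic claim.

## Problem sizes and determinism

All randomized steps take explicit seeds and are deterministic given them
(including UMAP and the autoencoders).  The test suite and the acceptance
script run cohorts of ~100 clonotypes / ~2,700 cells / 300 genes, 10–20 seeds
for recovery statistics and 100 seeds for the pure-noise exchangeability
check; these sizes put every statistic comfortably inside its tolerance while
keeping a full run to a few minutes on one CPU.  Spearman-based checks of
reference-prediction use an 8-cluster graded-contraction cohort because a
4-cluster cohort cannot reach p < 0.05 at n = 4 (the minimal two-sided
Spearman p is 1/12).
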