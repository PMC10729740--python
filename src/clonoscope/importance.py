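"""Factor-importance analysis: per-omic autoencoder latents, latent-phenotype
correlation counting against an alpha-expectation, and the equal-importance
chi-square test; plus the plasma-protein / transcriptomic-PC intersection
analysis.

Each candidate factor block (TCR sequence features, plasma proteome, HLA
alleles, dendritic-cell features) is compressed to 50 latent dimensions at its
native unit level, latents are broadcast to cells, and every (latent,
phenotype-dimension) pair is Pearson-tested.  Under the null that a factor
carries no phenotype information, the number of significant pairs is
``n_latents * n_phenotype_dims * alpha``; the chi-square test asks whether the
observed counts split equally across factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import chisquare
from scipy.stats import t as t_dist
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score
from sklearn.neural_network import MLPRegressor

from .errors import ClonoscopeError
from .phenotype import _dense, score_signature
from .records import AA_ALPHABET, ClonotypeRecord

OMIC_NAMES = ("tcr", "plasma", "hla", "cdc")


@dataclass
class OmicBlock:
    """One factor block at its native unit level (clonotype / patient-timepoint
    / patient), as a units x features matrix."""

    name: str
    level: str
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.matrix) < 2:
            raise ClonoscopeError(f"omic {self.name!r} needs at least 2 units")
        if self.matrix.isna().any().any():
            raise ClonoscopeError(f"omic {self.name!r} contains missing values")


@dataclass
class LatentBlock:
    """50-dimensional autoencoder bottleneck per unit, with the training loss
    trajectory and the mean squared reconstruction error on the standardized
    input."""

    name: str
    latents: pd.DataFrame
    loss_curve: list[float]
    reconstruction_mse: float = float("nan")


def encode_omic(
    block: OmicBlock, seed: int = 0, max_iter: int = 25, n_latents: int = 50, tol: float = 1e-4
) -> LatentBlock:
    """Train a 200-100-50-100-200 ReLU autoencoder on the standardized block
    and return the 50-unit bottleneck activations.

    Training uses the adam optimizer with a squared-error objective for at
    most ``max_iter`` epochs, stopping early when the relative loss change
    drops below ``tol``.  Deterministic for a fixed seed.
    """
    X = block.matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ClonoscopeError(f"omic {block.name!r}: need at least 3 units to train")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ClonoscopeError(
            f"omic {block.name!r}: every feature has zero variance after the "
            "standardization guard dropped them all"
        )
    if not keep.all():
        warnings.warn(
            f"omic {block.name!r}: dropping {int((~keep).sum())} zero-variance features",
            stacklevel=2,
        )
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    model = MLPRegressor(
        hidden_layer_sizes=(200, 100, n_latents, 100, 200),
        activation="relu",
        solver="adam",
        max_iter=max_iter,
        random_state=seed,
        tol=tol,
        n_iter_no_change=2,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, Xs)
    h = Xs
    bottleneck = None
    n_layers = len(model.coefs_)
    for layer in range(n_layers):
        h = h @ model.coefs_[layer] + model.intercepts_[layer]
        if layer < n_layers - 1:  # ReLU on hidden layers, identity on output
            h = np.maximum(h, 0.0)
        if layer == 2:
            bottleneck = h.copy()
    recon_mse = float(((h - Xs) ** 2).mean())
    latents = pd.DataFrame(
        bottleneck,
        index=block.matrix.index,
        columns=[f"latent_{i}" for i in range(bottleneck.shape[1])],
    )
    return LatentBlock(
        name=block.name,
        latents=latents,
        loss_curve=list(model.loss_curve_),
        reconstruction_mse=recon_mse,
    )


def derive_phenotype_dims(
    adata: ad.AnnData,
    mode: str = "pcs",
    n_pcs: int = 50,
    signatures: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Cell-level phenotype dimensions: expression PCs, signature scores, or both.

    ``adata`` must hold normalized expression.  ``n_pcs`` is clipped (with a
    warning) to the matrix rank bound min(cells, genes).
    """
    if mode not in ("pcs", "signatures", "both"):
        raise ClonoscopeError(f"unknown phenotype mode {mode!r}")
    parts = []
    if mode in ("pcs", "both"):
        X = _dense(adata.X)
        limit = min(X.shape)
        if n_pcs > limit:
            warnings.warn(f"n_pcs={n_pcs} clipped to {limit}", stacklevel=2)
            n_pcs = limit
        pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
        parts.append(
            pd.DataFrame(pcs, index=adata.obs_names, columns=[f"PC{i+1}" for i in range(n_pcs)])
        )
    if mode in ("signatures", "both"):
        if not signatures:
            raise ClonoscopeError("signature mode requires a signatures dict")
        sigs = {name: score_signature(adata, genes) for name, genes in signatures.items()}
        parts.append(pd.DataFrame(sigs))
    return pd.concat(parts, axis=1)


@dataclass
class ImportanceTable:
    """Observed vs expected significant latent-phenotype correlations per omic."""

    counts: pd.DataFrame
    chi2: float
    chi2_p: float
    df: int
    alpha: float
    total_observed: int

    @property
    def observed(self) -> pd.Series:
        return self.counts.set_index("omic")["observed"]

    @property
    def diff(self) -> pd.Series:
        return self.counts.set_index("omic")["observed_minus_expected"]

    @property
    def chi2_expected_per_omic(self) -> float:
        """Equal-importance null: each omic is expected to carry an equal share
        (1/n_omics) of the total observed significant correlations."""
        return self.total_observed / len(self.counts)


def count_significant(
    latent_blocks: list[LatentBlock],
    phenotype: pd.DataFrame,
    unit_maps: dict[str, pd.Series],
    alpha: float = 0.05,
) -> ImportanceTable:
    """Count significant latent-phenotype Pearson correlations per omic.

    Unit-level latents are broadcast to cells through ``unit_maps`` (per-cell
    unit ids, indexed like ``phenotype``); every (latent dim, phenotype dim)
    pair is tested two-sided at ``alpha``.  The expectation per omic is
    ``n_valid_pairs * alpha`` (latents constant after broadcast are skipped
    and the denominator adjusted).  The chi-square compares the observed
    per-omic counts to an equal split of their total.
    """
    n_cells = len(phenotype)
    P = phenotype.to_numpy(dtype=float)
    P = P - P.mean(axis=0)
    p_sd = P.std(axis=0, ddof=0)
    valid_p = p_sd > 0
    P[:, valid_p] = P[:, valid_p] / p_sd[valid_p]
    rows = []
    for block in latent_blocks:
        cell_units = unit_maps[block.name]
        L = block.latents.loc[cell_units].to_numpy(dtype=float)
        L = L - L.mean(axis=0)
        l_sd = L.std(axis=0, ddof=0)
        valid_l = l_sd > 0
        n_skipped = int((~valid_l).sum()) * int(valid_p.sum()) + int(valid_l.sum()) * int(
            (~valid_p).sum()
        ) + int((~valid_l).sum()) * int((~valid_p).sum())
        if n_skipped:
            warnings.warn(
                f"omic {block.name!r}: skipping {n_skipped} degenerate latent-phenotype pairs",
                stacklevel=2,
            )
        L = L[:, valid_l] / l_sd[valid_l]
        r = (L.T @ P[:, valid_p]) / n_cells
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t_vals = r * np.sqrt((n_cells - 2) / (1 - r**2))
        pvals = 2 * t_dist.sf(np.abs(t_vals), df=n_cells - 2)
        n_pairs = r.size
        observed = int((pvals < alpha).sum())
        expected = n_pairs * alpha
        rows.append(
            {
                "omic": block.name,
                "observed": observed,
                "expected": expected,
                "observed_minus_expected": observed - expected,
                "n_pairs": n_pairs,
                "n_skipped_pairs": n_skipped,
            }
        )
    counts = pd.DataFrame(rows)
    total = int(counts["observed"].sum())
    k = len(counts)
    if total == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p = chisquare(counts["observed"].to_numpy(), f_exp=np.full(k, total / k))
    return ImportanceTable(
        counts=counts, chi2=float(chi2), chi2_p=float(p), df=k - 1, alpha=alpha,
        total_observed=total,
    )


# ---------------------------------------------------------------------------
# Omic feature construction
# ---------------------------------------------------------------------------


def tcr_feature_block(clonotypes: list[ClonotypeRecord]) -> OmicBlock:
    """Clonotype-level TCR sequence features: one-hot V/J usage for both
    chains plus CDR3 length and amino-acid composition (20 frequencies) per
    chain."""
    ids = [r.clonotype_id for r in clonotypes]
    frames = []
    for attr in ("va", "ja", "vb", "jb"):
        col = pd.Series([getattr(r, attr) for r in clonotypes], index=ids)
        frames.append(pd.get_dummies(col, prefix=attr).astype(float))
    for chain, attr in (("a", "cdr3a"), ("b", "cdr3b")):
        seqs = [getattr(r, attr) for r in clonotypes]
        comp = np.array(
            [[s.count(aa) / len(s) for aa in AA_ALPHABET] for s in seqs]
        )
        frames.append(
            pd.DataFrame(comp, index=ids, columns=[f"cdr3{chain}_frac_{aa}" for aa in AA_ALPHABET])
        )
        frames.append(pd.DataFrame({f"cdr3{chain}_length": [len(s) for s in seqs]}, index=ids))
    return OmicBlock(name="tcr", level="clonotype", matrix=pd.concat(frames, axis=1))


def cohort_omic_blocks(cohort) -> tuple[list[OmicBlock], dict[str, pd.Series]]:
    """Build the four standard omic blocks and per-cell unit maps from a
    synthetic cohort (see :mod:`clonoscope.synthetic`)."""
    obs = cohort.cells.obs
    blocks = [
        tcr_feature_block(cohort.clonotypes),
        OmicBlock(name="plasma", level="patient-timepoint", matrix=cohort.plasma),
        OmicBlock(name="hla", level="patient", matrix=cohort.hla.astype(float)),
        OmicBlock(name="cdc", level="patient", matrix=cohort.cdc),
    ]
    unit_maps = {
        "tcr": obs["clonotype_id"].astype(str),
        "plasma": obs["patient_id"].astype(str) + "|" + obs["timepoint"].astype(str),
        "hla": obs["patient_id"].astype(str),
        "cdc": obs["patient_id"].astype(str),
    }
    return blocks, unit_maps


def importance_pipeline(
    cohort, seed: int = 0, alpha: float = 0.05, n_pcs: int = 50, max_iter: int = 25
) -> ImportanceTable:
    """End-to-end factor-importance comparison on a cohort: normalize, derive
    phenotype PCs, encode each omic, count significant correlations."""
    from .phenotype import normalize_log_cpm

    norm = normalize_log_cpm(cohort.cells)
    phenotype = derive_phenotype_dims(norm, mode="pcs", n_pcs=n_pcs)
    blocks, unit_maps = cohort_omic_blocks(cohort)
    latents = [encode_omic(b, seed=seed, max_iter=max_iter) for b in blocks]
    unit_maps = {k: v.loc[norm.obs_names] for k, v in unit_maps.items()}
    return count_significant(latents, phenotype, unit_maps, alpha=alpha)


# ---------------------------------------------------------------------------
# Plasma-protein / transcriptomic-PC intersection analysis
# ---------------------------------------------------------------------------


@dataclass
class ProteinPCGrid:
    """Ward-clustered protein x transcriptomic-PC correlation structure."""

    corr: pd.DataFrame
    pvals: pd.DataFrame
    protein_clusters: pd.Series
    pc_clusters: pd.Series
    k_proteins: int
    k_pcs: int
    silhouette_proteins: dict[int, float] = field(default_factory=dict)
    silhouette_pcs: dict[int, float] = field(default_factory=dict)


def _ward_rows(matrix: np.ndarray, k_range) -> tuple[np.ndarray, int, dict[int, float]]:
    n = matrix.shape[0]
    k_values = [k for k in k_range if 1 < k <= n - 1]
    if not k_values:
        raise ClonoscopeError(f"{n} rows cannot support any k in {list(k_range)}")
    Z = linkage(pdist(matrix), method="ward")
    sil: dict[int, float] = {}
    parts: dict[int, np.ndarray] = {}
    for k in k_values:
        part = fcluster(Z, t=k, criterion="maxclust")
        parts[k] = part
        sil[k] = (
            float(silhouette_score(matrix, part)) if len(np.unique(part)) > 1 else np.nan
        )
    finite = {k: v for k, v in sil.items() if not np.isnan(v)}
    best_k = min(finite, key=lambda k: (-finite[k], k)) if finite else min(k_values)
    return parts[best_k], best_k, sil


def protein_pc_intersections(
    plasma: pd.DataFrame,
    pc_by_unit: pd.DataFrame,
    k_range: range = range(3, 11),
) -> ProteinPCGrid:
    """Correlate individual plasma proteins with transcriptomic PCs (both at
    the patient-timepoint level) and Ward-cluster rows and columns.

    ``plasma`` is units x proteins and ``pc_by_unit`` units x PCs on a shared
    unit index; k for each axis is chosen by maximal silhouette over
    ``k_range``.
    """
    common = plasma.index.intersection(pc_by_unit.index)
    if len(common) < 3:
        raise ClonoscopeError("need at least 3 shared patient-timepoint units")
    X = plasma.loc[common].to_numpy(dtype=float)
    Y = pc_by_unit.loc[common].to_numpy(dtype=float)
    n = len(common)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0, ddof=0) == 0, np.inf, X.std(axis=0, ddof=0))
    Ys = (Y - Y.mean(axis=0)) / np.where(Y.std(axis=0, ddof=0) == 0, np.inf, Y.std(axis=0, ddof=0))
    r = (Xs.T @ Ys) / n
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t_vals = r * np.sqrt((n - 2) / (1 - r**2))
    pv = 2 * t_dist.sf(np.abs(t_vals), df=n - 2)
    corr = pd.DataFrame(r, index=plasma.columns, columns=pc_by_unit.columns)
    pvals = pd.DataFrame(pv, index=plasma.columns, columns=pc_by_unit.columns)
    prot_part, k_prot, sil_prot = _ward_rows(corr.to_numpy(), k_range)
    pc_part, k_pc, sil_pc = _ward_rows(corr.to_numpy().T, k_range)
    return ProteinPCGrid(
        corr=corr,
        pvals=pvals,
        protein_clusters=pd.Series(prot_part, index=corr.index),
        pc_clusters=pd.Series(pc_part, index=corr.columns),
        k_proteins=k_prot,
        k_pcs=k_pc,
        silhouette_proteins=sil_prot,
        silhouette_pcs=sil_pc,
    )


def intersection_scores(
    grid: ProteinPCGrid,
    protein_cluster: int,
    pc_cluster: int,
    plasma: pd.DataFrame,
    cell_pcs: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.Series, pd.Series]:
    """Protein and mRNA scores for one (protein-cluster, PC-cluster) intersection.

    The protein score per patient-timepoint is the mean standardized level of
    the cluster's proteins significantly correlated (p < alpha) with any PC in
    the PC cluster; the mRNA score per cell is the mean of the reciprocally
    significant PC columns.
    """
    prots = grid.protein_clusters.index[grid.protein_clusters == protein_cluster]
    pcs = grid.pc_clusters.index[grid.pc_clusters == pc_cluster]
    if len(prots) == 0 or len(pcs) == 0:
        raise ClonoscopeError("empty intersection: no proteins or PCs in the chosen clusters")
    sub_p = grid.pvals.loc[prots, pcs]
    sig_prots = sub_p.index[(sub_p < alpha).any(axis=1)]
    sig_pcs = sub_p.columns[(sub_p < alpha).any(axis=0)]
    if len(sig_prots) == 0 or len(sig_pcs) == 0:
        raise ClonoscopeError("empty intersection: no significant protein-PC correlations")
    z = (plasma[sig_prots] - plasma[sig_prots].mean()) / plasma[sig_prots].std(ddof=0)
    protein_score = z.mean(axis=1).rename("protein_score")
    mrna_score = cell_pcs[sig_pcs].mean(axis=1).rename("mrna_score")
    return protein_score, mrna_score
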