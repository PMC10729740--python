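"""Expression normalization, marker genes, gene modules, signatures, surface
proteins and embedding-density diffusion.

Cells are carried as :class:`anndata.AnnData`: raw counts in ``X``, cell
metadata (clonotype, patient, timepoint, batch) in ``obs``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import ClonoscopeError


def normalize_log_cpm(adata: ad.AnnData) -> ad.AnnData:
    """Return a copy with X = ln(1 + 1e6 * count / cell_total).

    Cells with zero total counts cannot be normalized and are excluded with a
    warning.  Sparsity is preserved (zero counts map to zero).
    """
    X = adata.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} zero-count cells", stacklevel=2)
    out = adata[keep].copy()
    X = out.X
    scale = 1e6 / totals[keep]
    if sp.issparse(X):
        X = X.tocsr().astype(float)
        X = sp.diags(scale) @ X
        X.data = np.log1p(X.data)
        out.X = X
    else:
        out.X = np.log1p(np.asarray(X, dtype=float) * scale[:, None])
    return out


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def rank_marker_genes(adata: ad.AnnData, labels: pd.Series | np.ndarray) -> dict:
    """One-vs-rest Mann-Whitney U marker genes per label on normalized data.

    Returns ``{label: DataFrame(gene, U, p, p_adj, lfc)}`` sorted by p then by
    descending fold change.  P values are Benjamini-Hochberg adjusted across
    genes within each label; genes constant across all compared cells get
    p = 1.  ``lfc`` is the difference of group means on the log scale divided
    by ln 2 (a log2 fold change of normalized expression).
    """
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ClonoscopeError("need at least 2 labels for marker-gene ranking")
    if (counts < 3).any():
        small = counts[counts < 3]
        raise ClonoscopeError(
            "labels with fewer than 3 cells: " + ", ".join(map(str, small.index))
        )
    X = _dense(adata.X)
    genes = np.asarray(adata.var_names)
    out = {}
    for label in counts.index:
        in_group = (labels == label).values
        Xg, Xr = X[in_group], X[~in_group]
        stats = np.empty(X.shape[1])
        pvals = np.empty(X.shape[1])
        for g in range(X.shape[1]):
            a, b = Xg[:, g], Xr[:, g]
            if np.ptp(np.concatenate([a, b])) == 0:
                stats[g] = len(a) * len(b) / 2.0
                pvals[g] = 1.0
                continue
            res = mannwhitneyu(a, b, alternative="two-sided")
            stats[g], pvals[g] = res.statistic, res.pvalue
        p_adj = multipletests(pvals, method="fdr_bh")[1]
        lfc = (Xg.mean(axis=0) - Xr.mean(axis=0)) / np.log(2)
        df = pd.DataFrame({"gene": genes, "U": stats, "p": pvals, "p_adj": p_adj, "lfc": lfc})
        out[label] = df.sort_values(["p", "lfc"], ascending=[True, False]).reset_index(drop=True)
    return out


@dataclass
class GeneModuleSet:
    """Disjoint co-expression modules over the selected marker genes."""

    modules: dict[int, list[str]]
    k: int
    silhouette_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def gene_to_module(self) -> dict[str, int]:
        return {g: m for m, genes in self.modules.items() for g in genes}


def discover_modules(
    adata: ad.AnnData,
    deg_tables: dict,
    top_n: int = 25,
    k_range: range = range(10, 21),
) -> GeneModuleSet:
    """Cluster top marker genes into co-expression modules.

    The union of the ``top_n`` lowest-p genes per label is correlated
    gene-by-gene (Pearson, on normalized expression), Ward-clustered on the
    distance 1 - r, and the module count k is chosen from ``k_range`` by the
    highest mean silhouette on that same distance (ties go to the smallest k).
    Constant genes are dropped with a warning before correlation.
    """
    selected: list[str] = []
    for df in deg_tables.values():
        for g in df["gene"].head(top_n):
            if g not in selected:
                selected.append(g)
    X = _dense(adata[:, selected].X)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant genes before correlation",
                      stacklevel=2)
        selected = [g for g, k_ in zip(selected, keep) if k_]
        X = X[:, keep]
    n_genes = len(selected)
    k_values = [k for k in k_range if 1 < k <= n_genes - 1]
    if not k_values:
        raise ClonoscopeError(
            f"{n_genes} usable genes cannot support any k in {list(k_range)}"
        )
    corr = np.corrcoef(X.T)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="ward")

    sil: dict[int, float] = {}
    partitions: dict[int, np.ndarray] = {}
    for k in k_values:
        part = fcluster(Z, t=k, criterion="maxclust")
        partitions[k] = part
        if len(np.unique(part)) < 2 or np.ptp(dist) <= 1e-10:
            sil[k] = np.nan
            continue
        sil[k] = float(silhouette_score(dist, part, metric="precomputed"))
    if all(np.isnan(v) for v in sil.values()):
        warnings.warn("silhouette undefined for every candidate k (degenerate geometry); "
                      "falling back to the smallest k", stacklevel=2)
        best_k = min(k_values)
    else:
        best = max(v for v in sil.values() if not np.isnan(v))
        best_k = min(k for k, v in sil.items() if not np.isnan(v) and v == best)
    part = partitions[best_k]
    modules: dict[int, list[str]] = {}
    for new, old in enumerate(pd.unique(part)):
        modules[new] = [g for g, m in zip(selected, part) if m == old]
    return GeneModuleSet(modules=modules, k=len(modules), silhouette_by_k=sil)


def score_signature(adata: ad.AnnData, gene_list: list[str]) -> pd.Series:
    """Per-cell signature score: mean normalized expression over listed genes
    present in the matrix.  Missing genes are reported with a warning; if no
    listed gene is present an error is raised."""
    present = [g for g in gene_list if g in adata.var_names]
    missing = [g for g in gene_list if g not in adata.var_names]
    if not present:
        raise ClonoscopeError("none of the signature genes are in the matrix")
    if missing:
        warnings.warn(f"{len(missing)} signature genes missing (e.g. {missing[:3]})",
                      stacklevel=2)
    X = _dense(adata[:, present].X)
    return pd.Series(X.mean(axis=1), index=adata.obs_names)


def batch_standardize_signatures(
    signatures: pd.DataFrame, batches: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Center and unit-scale each signature column within each batch.

    This removes additive/multiplicative per-batch shifts (the stand-in for
    iterative batch integration; see the methods note).  Zero-variance columns
    become 0; singleton batches are left uncentered with a warning.
    """
    batches = pd.Series(np.asarray(batches), index=signatures.index)
    out = signatures.astype(float).copy()
    for batch, idx in signatures.groupby(batches).groups.items():
        if len(idx) < 2:
            warnings.warn(f"batch {batch!r} has a single cell; left uncentered", stacklevel=2)
            continue
        block = out.loc[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        centered = block - mu
        centered = centered.div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
        out.loc[idx] = centered
    return out


def normalize_surface_proteins(
    protein_counts: pd.DataFrame, background_proteins: list[str]
) -> tuple[pd.DataFrame, pd.Index]:
    """Normalize CITE-seq surface-protein counts against background antibodies.

    Each cell's proteins are z-scored relative to that cell's own mean/SD of
    ln(1+count) over the background (isotype-like) antibodies.  Cells whose
    background SD is zero cannot be scaled; they are flagged (returned index)
    and their z values set to 0.
    """
    if len(background_proteins) < 2:
        raise ClonoscopeError("need at least 2 background proteins")
    missing = [p for p in background_proteins if p not in protein_counts.columns]
    if missing:
        raise ClonoscopeError(f"background proteins not in matrix: {missing}")
    logc = np.log1p(protein_counts.astype(float))
    bg = logc[background_proteins]
    mu = bg.mean(axis=1)
    sd = bg.std(axis=1, ddof=0)
    flagged = protein_counts.index[sd == 0]
    if len(flagged):
        warnings.warn(f"{len(flagged)} cells with zero background SD flagged and zeroed",
                      stacklevel=2)
    z = logc.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    z.loc[flagged] = 0.0
    return z, flagged


def diffuse_embedding_density(
    coords: np.ndarray,
    members: np.ndarray,
    k: int = 5,
    iterations: int = 5,
) -> np.ndarray:
    """Gaussian density of member cells on a 2-D embedding, then kNN diffusion.

    The kernel density (Scott-rule bandwidth over member coordinates) is
    min-max scaled to [0, 1] and propagated for ``iterations`` steps along the
    mass-conserving transpose of the row-normalized (k+1)-neighbor adjacency
    (self-loops included), so total density is conserved exactly.
    """
    coords = np.asarray(coords, dtype=float)
    members = np.asarray(members, dtype=bool)
    n = len(coords)
    if n < k + 1:
        raise ClonoscopeError(f"{n} cells but k={k}; need at least k+1")
    if not members.any():
        warnings.warn("no member cells; returning a zero density", stacklevel=2)
        return np.zeros(n)

    mem = coords[members]
    h = mem.std(axis=0, ddof=0) * max(len(mem), 2) ** (-1 / 6)
    fallback = coords.std(axis=0, ddof=0) * n ** (-1 / 6)
    h = np.where(h > 0, h, np.where(fallback > 0, fallback, 1.0))
    diff = (coords[:, None, :] - mem[None, :, :]) / h[None, None, :]
    density = np.exp(-0.5 * (diff**2).sum(axis=2)).sum(axis=1)

    lo, hi = density.min(), density.max()
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):  # constant up to roundoff
        density = np.ones(n)
    else:
        density = (density - lo) / (hi - lo)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k + 1)
    cols = idx.ravel()
    A = sp.csr_matrix((np.full(rows.shape, 1.0 / (k + 1)), (rows, cols)), shape=(n, n))
    for _ in range(iterations):
        density = A.T @ density
    return np.asarray(density)
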