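"""Diffusion-component sequence similarity between TCR clusters.

The weighted clonotype kNN graph is turned into a diffusion map; pseudotime
from a root clonotype is the Euclidean distance in eigenvalue-scaled diffusion
coordinates.  The cluster-pair similarity score of a clonotype subtracts its
mean pseudotime over roots in cluster A from the mean over roots in cluster B,
so positive scores mean "closer in sequence space to cluster A".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr
from sklearn.neighbors import NearestNeighbors

from .errors import ClonoscopeError
from .tcr_space import ClusterAssignment, NeighborGraph


@dataclass
class DiffusionSpace:
    """Eigenvalue-scaled diffusion coordinates of a clonotype graph.

    ``phi`` holds per-node coordinates phi_k = (lambda_k / (1 - lambda_k)) psi_k
    for the top nontrivial eigenpairs of the graph's random-walk transition
    matrix, computed per connected component (``components`` labels them).
    Distances across components are treated as infinite.
    """

    ids: list[str]
    phi: np.ndarray
    psi: np.ndarray
    eigenvalues: dict[int, np.ndarray]
    components: np.ndarray
    n_dcs: int

    def index_of(self, clonotype_id: str) -> int:
        try:
            return self.ids.index(clonotype_id)
        except ValueError:
            raise ClonoscopeError(f"unknown clonotype {clonotype_id!r}") from None


@dataclass
class SimilarityScore:
    """Per-clonotype sequence-similarity score between two clusters.

    Scores above zero mean the clonotype is closer (in diffusion pseudotime)
    to ``cluster_a``; below zero, closer to ``cluster_b``.
    """

    scores: pd.Series
    cluster_a: int
    cluster_b: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "clonotype_id": self.scores.index,
                "score": self.scores.values,
                "clusterA": self.cluster_a,
                "clusterB": self.cluster_b,
            }
        )


def diffusion_components(graph: NeighborGraph, n_dcs: int = 15) -> DiffusionSpace:
    """Compute the top ``n_dcs`` nontrivial diffusion components of the graph.

    The kernel is row-normalized into a transition matrix; its symmetric
    conjugate is densely eigendecomposed per connected component and the
    trivial constant eigenvector is dropped.  Components smaller than
    ``n_dcs + 1`` contribute as many eigenpairs as they support.
    """
    W = graph.weights
    n = graph.n_nodes
    n_comp, comp_labels = connected_components(W, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"graph has {n_comp} connected components; diffusion computed per "
            "component and cross-component pseudotime is infinite",
            stacklevel=2,
        )
    phi = np.zeros((n, n_dcs))
    psi = np.zeros((n, n_dcs))
    eigenvalues: dict[int, np.ndarray] = {}
    for comp in range(n_comp):
        nodes = np.flatnonzero(comp_labels == comp)
        if len(nodes) == 1:
            eigenvalues[comp] = np.empty(0)
            continue
        Wc = W[nodes][:, nodes].toarray()
        deg = Wc.sum(axis=1)
        inv_sqrt = 1.0 / np.sqrt(deg)
        S = Wc * inv_sqrt[:, None] * inv_sqrt[None, :]
        vals, vecs = np.linalg.eigh(S)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        # drop the trivial stationary eigenpair (eigenvalue 1)
        vals, vecs = vals[1:], vecs[:, 1:]
        k = min(n_dcs, len(vals))
        lam = np.clip(vals[:k], -1 + 1e-12, 1 - 1e-12)
        psi_c = vecs[:, :k] * inv_sqrt[:, None]
        phi[np.ix_(nodes, np.arange(k))] = psi_c * (lam / (1 - lam))[None, :]
        psi[np.ix_(nodes, np.arange(k))] = psi_c
        eigenvalues[comp] = vals[:k]
    return DiffusionSpace(
        ids=list(graph.ids),
        phi=phi,
        psi=psi,
        eigenvalues=eigenvalues,
        components=comp_labels,
        n_dcs=n_dcs,
    )


def pseudotime_from_root(space: DiffusionSpace, root: str) -> pd.Series:
    """Diffusion pseudotime from a root clonotype: ||phi(i) - phi(root)||.

    Nodes in other connected components get ``inf``.
    """
    r = space.index_of(root)
    vals = np.linalg.norm(space.phi - space.phi[r], axis=1)
    vals[space.components != space.components[r]] = np.inf
    return pd.Series(vals, index=space.ids, name="pseudotime")


def pairwise_cluster_similarity(
    space: DiffusionSpace,
    clusters: ClusterAssignment,
    cluster_a: int,
    cluster_b: int,
) -> SimilarityScore:
    """Score every clonotype by sequence similarity to cluster A vs cluster B.

    s(i) = mean over roots r in B of dpt_r(i) - mean over roots r in A of
    dpt_r(i); swapping A and B negates the score exactly.
    """
    labels = clusters.labels.reindex(space.ids)
    roots_a = np.flatnonzero(labels.values == cluster_a)
    roots_b = np.flatnonzero(labels.values == cluster_b)
    if len(roots_a) == 0 or len(roots_b) == 0:
        raise ClonoscopeError(
            f"empty cluster among ({cluster_a}, {cluster_b}); both must have members"
        )
    s = _mean_dpt(space, roots_b) - _mean_dpt(space, roots_a)
    return SimilarityScore(
        scores=pd.Series(s, index=space.ids, name="similarity"),
        cluster_a=cluster_a,
        cluster_b=cluster_b,
    )


def _mean_dpt(space: DiffusionSpace, roots: np.ndarray) -> np.ndarray:
    d = cdist(space.phi, space.phi[roots])
    cross = space.components[:, None] != space.components[roots][None, :]
    d[cross] = np.inf
    return d.mean(axis=1)


def binned_association(
    score: SimilarityScore | pd.Series,
    variable: pd.Series,
    n_bins: int = 25,
) -> tuple[float, float, pd.DataFrame]:
    """Correlate a similarity score with a clonotype-level variable after
    binning the score axis.

    The score range is cut into ``n_bins`` equal-width bins; empty bins are
    dropped and Pearson r/p is computed between the per-bin mean score and the
    per-bin mean variable (so a variable equal to the score correlates at
    exactly 1).  Returns ``(r, p, bin_table)``; the table also carries the
    geometric bin centers.
    """
    s = score.scores if isinstance(score, SimilarityScore) else score
    df = pd.DataFrame({"score": s, "var": variable.reindex(s.index)})
    df = df[np.isfinite(df["score"]) & np.isfinite(df["var"])]
    if df.empty:
        raise ClonoscopeError("no finite (score, variable) pairs to bin")
    lo, hi = df["score"].min(), df["score"].max()
    if hi == lo:
        raise ClonoscopeError("constant score: fewer than 3 nonempty bins")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(df["score"], edges[1:-1]), 0, n_bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    table = (
        pd.DataFrame({"bin": which, "var": df["var"].values, "score": df["score"].values})
        .groupby("bin")
        .agg(bin_mean=("var", "mean"), bin_score=("score", "mean"))
    )
    table["bin_center"] = centers[table.index]
    if len(table) < 3:
        raise ClonoscopeError(f"only {len(table)} nonempty bins; need at least 3")
    r, p = pearsonr(table["bin_score"], table["bin_mean"])
    return float(r), float(p), table


def cluster_connectivity(
    space: DiffusionSpace,
    clusters: ClusterAssignment,
    k: int = 20,
) -> pd.DataFrame:
    """Cluster-level connectivity from a kNN graph in diffusion coordinates.

    For each unordered cluster pair the weight is the observed inter-cluster
    edge count divided by the count expected if edges were placed in
    proportion to cluster degree sums (the configuration null), clipped to
    [0, 1].  Neighbors are searched within connected components only.
    """
    n = len(space.ids)
    if n < k + 1:
        raise ClonoscopeError(f"{n} clonotypes but k={k}; need at least k+1")
    edges: set[tuple[int, int]] = set()
    for comp in np.unique(space.components):
        nodes = np.flatnonzero(space.components == comp)
        if len(nodes) < 2:
            continue
        kk = min(k, len(nodes) - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(space.phi[nodes])
        _, idx = nn.kneighbors(space.phi[nodes])
        for a, row in enumerate(idx):
            for b in row:
                if a != b:
                    i, j = int(nodes[a]), int(nodes[b])
                    edges.add((min(i, j), max(i, j)))
    labels = clusters.labels.reindex(space.ids).values
    deg = np.zeros(n)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    uniq = np.unique(labels)
    deg_sum = {c: deg[labels == c].sum() for c in uniq}
    m = len(edges)
    obs: dict[tuple[int, int], int] = {}
    for i, j in edges:
        a, b = labels[i], labels[j]
        if a != b:
            key = (min(a, b), max(a, b))
            obs[key] = obs.get(key, 0) + 1
    rows = []
    for ai in range(len(uniq)):
        for bi in range(ai + 1, len(uniq)):
            a, b = uniq[ai], uniq[bi]
            expected = deg_sum[a] * deg_sum[b] / (2.0 * m) if m else 0.0
            observed = obs.get((min(a, b), max(a, b)), 0)
            weight = float(np.clip(observed / expected, 0.0, 1.0)) if expected > 0 else 0.0
            rows.append({"cluster_a": a, "cluster_b": b, "observed": observed,
                         "expected": expected, "weight": weight})
    return pd.DataFrame(rows)
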