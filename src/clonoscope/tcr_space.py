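"""Paired-chain TCR distances, neighbor graphs, clustering and 2-D embeddings.

The distance is a TCRdist-style semimetric: a BLOSUM62-derived per-position
substitution penalty summed over the germline-encoded CDR1/CDR2/CDR2.5 loops
(weight 1 each) of both chains and over the junction-proximal CDR3 loops
(weight 3, trimmed of the conserved terminal residues).  Unequal-length loops
are aligned by inserting a single central gap block.  The triangle inequality
is not guaranteed and is never relied upon downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio.Align import substitution_matrices
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import ClonoscopeError, GermlineError, SequenceError
from .records import AA_ALPHABET, ClonotypeRecord

# ---------------------------------------------------------------------------
# Germline loop table for simulated gene names
# ---------------------------------------------------------------------------

#: Minimal germline table mapping simulated V gene names to their
#: (CDR1, CDR2, CDR2.5) loop sequences.  Real gene names are not covered;
#: distance computation falls back to CDR3-only mode for them (with a warning
#: in ``auto`` mode, or an error in ``germline`` mode).
SIM_GERMLINE: dict[str, tuple[str, str, str]] = {
    "TRAV1-S": ("RLLADK", "ALICIYC", "AGWN"),
    "TRAV2-S": ("FRLPNW", "WLMRYQP", "NQQP"),
    "TRAV3-S": ("SDVMKM", "AQGMFDQ", "VHSE"),
    "TRAV4-S": ("IHINPC", "DLDYQCC", "GLFL"),
    "TRAV5-S": ("MYGMDL", "SIMASEG", "FQQA"),
    "TRAV6-S": ("RISFDS", "PIMKEWI", "GTQR"),
    "TRAV7-S": ("GSSAPK", "MNCVQSR", "KDCV"),
    "TRAV8-S": ("ELQHHR", "NPTRVCA", "MMSW"),
    "TRAV9-S": ("IDGRHF", "YTCHFHH", "QIKK"),
    "TRAV10-S": ("HRDYYF", "WVCNFFP", "SIFF"),
    "TRAV11-S": ("AGACMS", "IFVFCTN", "TKNM"),
    "TRAV12-S": ("DFHSKE", "QDMLMRS", "PNPM"),
    "TRAV13-S": ("CRLPTD", "TGPLDTI", "YWAQ"),
    "TRAV14-S": ("QYKQDT", "KKATSKA", "WMKE"),
    "TRAV15-S": ("ILYCMW", "HRFKCFC", "QCMM"),
    "TRAV16-S": ("TRGQEV", "WSGPYGQ", "NLRW"),
    "TRBV1-S": ("GLYVNP", "PVAQYKR", "RFTS"),
    "TRBV2-S": ("LKQDQC", "QMEIKLS", "GAHQ"),
    "TRBV3-S": ("HPFEQG", "NPNWYNE", "DWEM"),
    "TRBV4-S": ("YHLEMI", "PTGGWWS", "EDKR"),
    "TRBV5-S": ("DKIYLM", "RSNCMMG", "GNIE"),
    "TRBV6-S": ("MECDRF", "CWHQQNI", "RTKM"),
    "TRBV7-S": ("LDIAHV", "YQHVGWA", "DGFL"),
    "TRBV8-S": ("SYTCGV", "NESSLTE", "QWFL"),
    "TRBV9-S": ("QGDGPM", "GEMLDCE", "NTCL"),
    "TRBV10-S": ("TNTYCH", "CADENQQ", "GTDL"),
    "TRBV11-S": ("LWLVEN", "WMNIAKV", "NHVD"),
    "TRBV12-S": ("TPNGDC", "HWRFPVK", "SYAQ"),
    "TRBV13-S": ("RAMKDQ", "AGWMDAY", "YYTQ"),
    "TRBV14-S": ("EHPRKA", "CCWIGMG", "EDYH"),
    "TRBV15-S": ("DKWQTK", "RRNSFPH", "WGKD"),
    "TRBV16-S": ("DSNTTG", "GQKRYLS", "TFDW"),
}

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def _penalty_table() -> np.ndarray:
    """20x20 substitution penalty: min(4, 4 - BLOSUM62), zero on the diagonal."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    table = np.zeros((n, n))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            if i != j:
                table[i, j] = min(4.0, 4.0 - float(blosum[a][b]))
    return table


_PENALTY = _penalty_table()


@dataclass(frozen=True)
class TcrDistParams:
    """Parameters of the TCRdist-style distance.

    ``mode`` is one of ``auto`` (use germline loops when every V gene is in
    the bundled table, otherwise fall back to CDR3-only with a warning),
    ``germline`` (require germline resolution, error on unknown genes) or
    ``cdr3`` (junction loops only).  ``chains`` selects which chains enter the
    distance; alpha-only distances are used for reference-based contraction
    prediction.
    """

    mode: str = "auto"
    chains: tuple[str, ...] = ("alpha", "beta")
    cdr3_weight: float = 3.0
    loop_weight: float = 1.0
    trim_n: int = 3
    trim_c: int = 2
    gap_penalty: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "germline", "cdr3"):
            raise ClonoscopeError(f"unknown distance mode {self.mode!r}")
        if not set(self.chains) <= {"alpha", "beta"} or not self.chains:
            raise ClonoscopeError(f"chains must be a nonempty subset of alpha/beta, got {self.chains}")


@dataclass
class ClonotypeDistanceMatrix:
    """Symmetric clonotype-by-clonotype distance matrix."""

    ids: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def _encode(seq: str, clonotype_id: str, chain: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.intp)
    except KeyError:
        for pos, aa in enumerate(seq):
            if aa not in _AA_INDEX:
                raise SequenceError(
                    f"unknown amino acid {aa!r} at position {pos} of {chain} loop in {clonotype_id}"
                ) from None
        raise


def _loop_distance(x: np.ndarray, y: np.ndarray, weight: float, gap_penalty: float) -> float:
    """Distance of one aligned loop pair with a single central gap block in
    the shorter sequence."""
    if len(x) > len(y):
        x, y = y, x
    m, n = len(x), len(y)
    gap = n - m
    sub = 0.0
    if m:
        lead = (m + 1) // 2
        tail = m - lead
        sub += _PENALTY[x[:lead], y[:lead]].sum()
        if tail:
            sub += _PENALTY[x[lead:], y[n - tail:]].sum()
    return weight * (sub + gap * gap_penalty)


def _resolve_loops(
    records: list[ClonotypeRecord], params: TcrDistParams
) -> tuple[bool, list[list[np.ndarray]]]:
    """Return (use_germline, per-record list of encoded loops)."""
    use_germline = params.mode in ("auto", "germline")
    if use_germline:
        missing = sorted(
            {
                gene
                for r in records
                for chain, gene in (("alpha", r.va), ("beta", r.vb))
                if chain in params.chains and gene not in SIM_GERMLINE
            }
        )
        if missing:
            if params.mode == "germline":
                raise GermlineError(
                    "V genes missing from the bundled germline table: " + ", ".join(missing)
                )
            warnings.warn(
                f"{len(missing)} V genes not in the bundled germline table "
                "(e.g. " + ", ".join(missing[:3]) + "); falling back to CDR3-only distances",
                stacklevel=3,
            )
            use_germline = False

    loops: list[list[np.ndarray]] = []
    for r in records:
        rec_loops: list[np.ndarray] = []
        for chain, v_gene, cdr3 in (("alpha", r.va, r.cdr3a), ("beta", r.vb, r.cdr3b)):
            if chain not in params.chains:
                continue
            if use_germline:
                for loop_seq in SIM_GERMLINE[v_gene]:
                    rec_loops.append(_encode(loop_seq, r.clonotype_id, chain))
            trimmed = cdr3[params.trim_n : len(cdr3) - params.trim_c]
            rec_loops.append(_encode(trimmed, r.clonotype_id, chain))
        loops.append(rec_loops)
    return use_germline, loops


def _pair_distance(
    loops_i: list[np.ndarray], loops_j: list[np.ndarray], params: TcrDistParams, use_germline: bool
) -> float:
    n_per_chain = 4 if use_germline else 1
    d = 0.0
    for k, (x, y) in enumerate(zip(loops_i, loops_j)):
        is_cdr3 = (k % n_per_chain) == n_per_chain - 1
        weight = params.cdr3_weight if is_cdr3 else params.loop_weight
        d += _loop_distance(x, y, weight, params.gap_penalty)
    return d


def compute_tcrdist(
    clonotypes: list[ClonotypeRecord],
    others: list[ClonotypeRecord] | None = None,
    params: TcrDistParams | None = None,
) -> ClonotypeDistanceMatrix:
    """Compute TCRdist-style distances between paired-chain clonotypes.

    With ``others=None`` the result is the symmetric within-set matrix (zero
    diagonal); otherwise a rectangular ``clonotypes x others`` matrix whose
    ``ids`` are the row ids.
    """
    params = params or TcrDistParams()
    if not clonotypes:
        raise ClonoscopeError("no clonotypes given")
    if others is None:
        use_germline, loops = _resolve_loops(clonotypes, params)
        n = len(clonotypes)
        out = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = _pair_distance(loops[i], loops[j], params, use_germline)
        return ClonotypeDistanceMatrix([r.clonotype_id for r in clonotypes], out)

    use_germline, loops = _resolve_loops(clonotypes + others, params)
    n, m = len(clonotypes), len(others)
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            out[i, j] = _pair_distance(loops[i], loops[n + j], params, use_germline)
    return ClonotypeDistanceMatrix([r.clonotype_id for r in clonotypes], out)


# ---------------------------------------------------------------------------
# Neighbor graph, clustering, embedding
# ---------------------------------------------------------------------------


@dataclass
class NeighborGraph:
    """Weighted k-nearest-neighbor graph over clonotypes.

    ``weights`` is a symmetric sparse matrix with entries in (0, 1] and no
    self-edges; ``pcs`` holds the PCA coordinates of the distance-matrix rows
    the graph was built in.
    """

    ids: list[str]
    weights: sp.csr_matrix
    knn_indices: np.ndarray
    knn_distances: np.ndarray
    pcs: np.ndarray
    n_neighbors: int
    graph_pcs: int

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def to_igraph(self):
        import igraph as ig

        coo = sp.triu(self.weights, k=1).tocoo()
        g = ig.Graph(
            n=self.n_nodes,
            edges=list(zip(coo.row.tolist(), coo.col.tolist())),
            edge_attrs={"weight": coo.data.tolist()},
        )
        return g


@dataclass
class ClusterAssignment:
    """Clonotype -> cluster labels plus the Leiden resolution that produced them."""

    labels: pd.Series
    resolution: float
    over_clustered_at_start: bool = False
    n_clusters_path: list[tuple[float, int]] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"clonotype_id": self.labels.index, "tcr_cluster": self.labels.values,
             "resolution": self.resolution}
        )


def build_graph(
    distances: ClonotypeDistanceMatrix,
    n_pcs: int = 50,
    n_neighbors: int = 30,
    graph_pcs: int = 20,
    local_scale_k: int = 7,
) -> NeighborGraph:
    """PCA-reduce the distance-matrix rows and build a kNN graph.

    Rows of the (centered) distance matrix are treated as feature vectors for
    PCA; neighbors are found in the first ``graph_pcs`` components with the
    Euclidean metric, and edge weights come from a locally adaptive Gaussian
    kernel w_ij = exp(-d_ij^2 / (sigma_i sigma_j)) with sigma_i the distance
    to the ``local_scale_k``-th neighbor, symmetrized by max.
    """
    n = len(distances.ids)
    if n < n_neighbors + 1:
        raise ClonoscopeError(
            f"{n} clonotypes but n_neighbors={n_neighbors}; use n_neighbors <= {n - 1}"
        )
    n_pcs_eff = min(n_pcs, n)
    pca = PCA(n_components=n_pcs_eff, svd_solver="full")
    pcs = pca.fit_transform(distances.values)
    coords = pcs[:, : min(graph_pcs, pcs.shape[1])]

    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    dists, idx = nn.kneighbors(coords)
    # drop self (guaranteed at distance 0; may not be first among duplicates)
    keep_d = np.empty((n, n_neighbors))
    keep_i = np.empty((n, n_neighbors), dtype=np.intp)
    for i in range(n):
        mask = idx[i] != i
        if mask.sum() == n_neighbors + 1:  # self missing among ties: drop last
            mask[-1] = False
        keep_d[i] = dists[i][mask][:n_neighbors]
        keep_i[i] = idx[i][mask][:n_neighbors]

    sigma = keep_d[:, min(local_scale_k, n_neighbors) - 1]
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = keep_i.ravel()
    denom = sigma[rows] * sigma[cols]
    d2 = keep_d.ravel() ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-d2 / denom)
    w[denom == 0] = np.where(d2[denom == 0] == 0, 1.0, 0.0)
    w = np.clip(w, 0.0, 1.0)
    mat = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    mat = mat.maximum(mat.T)
    mat.setdiag(0)
    mat.eliminate_zeros()
    return NeighborGraph(
        ids=list(distances.ids),
        weights=mat,
        knn_indices=keep_i,
        knn_distances=keep_d,
        pcs=pcs,
        n_neighbors=n_neighbors,
        graph_pcs=graph_pcs,
    )


def cluster_resolution_search(
    graph: NeighborGraph,
    start: float = 0.5,
    step: float = 0.01,
    max_res: float = 2.0,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden clustering at the highest resolution that avoids over-clustering.

    Resolutions ``start, start+step, ..., max_res`` are scanned; the returned
    partition is the one at the highest resolution for which no cluster falls
    below ``min_cluster_size`` members (the operational proxy for
    over-clustering).  If even the start resolution violates the rule, the
    start partition is returned with ``over_clustered_at_start`` set.
    """
    import leidenalg

    g = graph.to_igraph()
    weights = g.es["weight"] if g.ecount() else None
    resolutions = np.arange(start, max_res + step / 2, step)
    best: tuple[float, list[int]] | None = None
    start_partition: list[int] | None = None
    path: list[tuple[float, int]] = []
    for res in resolutions:
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=float(res),
            seed=seed,
            n_iterations=2,
        )
        membership = list(part.membership)
        sizes = np.bincount(membership)
        path.append((float(res), len(sizes)))
        if start_partition is None:
            start_partition = membership
        if sizes.min() >= min_cluster_size:
            best = (float(res), membership)

    over = best is None
    if over:
        warnings.warn(
            f"no resolution in [{start}, {max_res}] avoided clusters smaller than "
            f"{min_cluster_size}; returning the start-resolution partition",
            stacklevel=2,
        )
        best = (float(resolutions[0]), start_partition or [])
    res, membership = best
    labels = _relabel_by_size(np.asarray(membership))
    return ClusterAssignment(
        labels=pd.Series(labels, index=graph.ids, name="tcr_cluster"),
        resolution=res,
        over_clustered_at_start=over,
        n_clusters_path=path,
    )


def _relabel_by_size(membership: np.ndarray) -> np.ndarray:
    """Relabel communities 0..k-1 in decreasing size order (ties by old label)."""
    sizes = pd.Series(membership).value_counts()
    order = {old: new for new, old in enumerate(sizes.index)}
    return np.array([order[m] for m in membership], dtype=int)


def embed_2d(graph: NeighborGraph, seed: int = 0, min_dist: float = 0.3) -> pd.DataFrame:
    """2-D UMAP embedding of the graph's PC coordinates (deterministic per seed).

    Inputs too small for the UMAP optimizer (fewer than 5 points) fall back to
    the first two PCs, which preserves determinism and distinctness.
    """
    n = graph.n_nodes
    coords = graph.pcs[:, : graph.graph_pcs]
    if n < 5:
        out = np.zeros((n, 2))
        out[:, : min(2, coords.shape[1])] = coords[:, :2]
        return pd.DataFrame(out, index=graph.ids, columns=["umap1", "umap2"])
    import umap

    reducer = umap.UMAP(
        n_neighbors=min(graph.n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=seed,
        n_components=2,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        emb = reducer.fit_transform(coords)
    return pd.DataFrame(emb, index=graph.ids, columns=["umap1", "umap2"])
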