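"""Clonotype frequency tracking, contraction statistics, TRAV regression and
reference-based contraction prediction.

Contraction strength of a TCR cluster is
``C = log10(mean convalescent % + 1) - log10(mean acute % + 1)`` where acute
pools the T1/T2 draws and convalescent is T3; negative values mean the
cluster's share of the CD8 repertoire shrank after viral clearance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency, pearsonr, ttest_ind

from .errors import ClonoscopeError
from .records import ClonotypeRecord
from .tcr_space import ClonotypeDistanceMatrix, ClusterAssignment, TcrDistParams, compute_tcrdist

ACUTE_TIMEPOINTS = ("T1", "T2")
CONVALESCENT_TIMEPOINTS = ("T3",)


def clonotype_frequencies(
    cells: pd.DataFrame, totals: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-clonotype repertoire percentages per patient and timepoint.

    ``cells`` needs columns clonotype_id, patient_id, timepoint.  ``totals``
    (patient_id, timepoint, total_cells) supplies the repertoire denominator,
    e.g. the full count of high-quality CD8+ T cells; by default the cells
    table itself is the denominator, in which case percentages sum to 100 per
    patient-timepoint.  A clonotype seen anywhere for a patient gets explicit
    0 rows at that patient's other timepoints.
    """
    required = {"clonotype_id", "patient_id", "timepoint"}
    if not required <= set(cells.columns):
        raise ClonoscopeError(f"cells table missing columns: {required - set(cells.columns)}")
    counts = (
        cells.groupby(["patient_id", "timepoint", "clonotype_id"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    if totals is None:
        denom = (
            cells.groupby(["patient_id", "timepoint"], observed=True)
            .size()
            .rename("total_cells")
            .reset_index()
        )
    else:
        denom = totals[["patient_id", "timepoint", "total_cells"]]
    denom = denom[denom["total_cells"] > 0]

    # expand to every (patient clonotype) x (patient timepoint) combination
    pairs = counts[["patient_id", "clonotype_id"]].drop_duplicates()
    grid = pairs.merge(denom, on="patient_id")
    out = grid.merge(counts, on=["patient_id", "timepoint", "clonotype_id"], how="left")
    out["n_cells"] = out["n_cells"].fillna(0).astype(int)
    out["pct"] = 100.0 * out["n_cells"] / out["total_cells"]
    return out[["clonotype_id", "patient_id", "timepoint", "n_cells", "total_cells", "pct"]]


@dataclass
class ContractionTable:
    """Per-cluster contraction strengths with Welch tests."""

    per_cluster: pd.DataFrame
    acute_timepoints: tuple[str, ...]
    convalescent_timepoints: tuple[str, ...]

    @property
    def strengths(self) -> pd.Series:
        return self.per_cluster.set_index("cluster")["contraction_strength"]


def contraction_strength(
    frequencies: pd.DataFrame,
    clusters: ClusterAssignment | pd.Series,
    acute: tuple[str, ...] = ACUTE_TIMEPOINTS,
    convalescent: tuple[str, ...] = CONVALESCENT_TIMEPOINTS,
) -> ContractionTable:
    """Mean repertoire percentage per cluster at acute vs convalescent draws.

    Per cluster, the acute and convalescent per-clonotype percentage vectors
    (zeros included for absent draws) are averaged and compared with a
    two-sided Welch t-test; the contraction strength is the difference of
    log10(mean % + 1) values (negative = contraction).
    """
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    freq = frequencies.copy()
    freq["cluster"] = freq["clonotype_id"].map(labels)
    freq = freq[freq["cluster"].notna()]
    rows = []
    all_clusters = sorted(pd.unique(labels.dropna()))
    grouped = dict(iter(freq.groupby("cluster")))
    for cluster in all_clusters:
        grp = grouped.get(cluster)
        if grp is None:
            raise ClonoscopeError(
                f"cluster {cluster} lacks observations at acute or convalescent timepoints"
            )
        a = grp.loc[grp["timepoint"].isin(acute), "pct"].values
        v = grp.loc[grp["timepoint"].isin(convalescent), "pct"].values
        if len(a) == 0 or len(v) == 0:
            raise ClonoscopeError(
                f"cluster {cluster} lacks observations at acute or convalescent timepoints"
            )
        mean_a, mean_v = float(a.mean()), float(v.mean())
        strength = float(np.log10(mean_v + 1) - np.log10(mean_a + 1))
        if len(a) > 1 and len(v) > 1 and (a.std() > 0 or v.std() > 0):
            t_stat, p = ttest_ind(a, v, equal_var=False)
        else:
            t_stat, p = 0.0, 1.0
        rows.append(
            {
                "cluster": cluster,
                "mean_acute_pct": mean_a,
                "mean_convalescent_pct": mean_v,
                "contraction_strength": strength,
                "t_stat": float(t_stat),
                "p": float(p),
                "n_acute_obs": len(a),
                "n_convalescent_obs": len(v),
            }
        )
    table = pd.DataFrame(rows).sort_values("cluster").reset_index(drop=True)
    return ContractionTable(table, acute, convalescent)


def correlate_contraction_features(
    strengths: pd.Series, cluster_features: pd.DataFrame
) -> pd.DataFrame:
    """Pearson-correlate per-cluster contraction with per-cluster feature means.

    ``cluster_features`` is clusters x features (typically acute-timepoint
    means of signature scores, TF activities or surface proteins).  Constant
    features have no defined correlation and are dropped with a note column.
    """
    common = strengths.index.intersection(cluster_features.index)
    if len(common) < 3:
        raise ClonoscopeError(f"need at least 3 clusters, got {len(common)}")
    c = strengths.loc[common].astype(float)
    rows = []
    for feature in cluster_features.columns:
        x = cluster_features.loc[common, feature].astype(float)
        if x.std(ddof=0) == 0 or c.std(ddof=0) == 0:
            rows.append({"feature": feature, "r": np.nan, "p": np.nan, "note": "constant"})
            continue
        r, p = pearsonr(c, x)
        rows.append({"feature": feature, "r": float(r), "p": float(p), "note": ""})
    return pd.DataFrame(rows)


@dataclass
class TravModel:
    """Cluster-level OLS of contraction strength on screened TRAV usage."""

    genes: list[str]
    coefficients: pd.Series
    intercept: float
    coef_pvalues: pd.Series
    predictions: pd.Series
    screen_pvalues: pd.Series
    dropped_collinear: list[str] = field(default_factory=list)


def trav_usage(
    clonotypes: list[ClonotypeRecord], clusters: ClusterAssignment | pd.Series
) -> pd.DataFrame:
    """Percent usage of each TRAV gene within each cluster."""
    labels = clusters.labels if isinstance(clusters, ClusterAssignment) else clusters
    df = pd.DataFrame(
        {"cluster": [labels.get(r.clonotype_id) for r in clonotypes],
         "va": [r.va for r in clonotypes]}
    ).dropna()
    usage = pd.crosstab(df["cluster"], df["va"])
    return 100.0 * usage.div(usage.sum(axis=1), axis=0)


def fit_trav_model(
    usage: pd.DataFrame, strengths: pd.Series, alpha: float = 0.05
) -> TravModel:
    """Screen TRAV genes by univariate correlation with contraction, then fit
    OLS of contraction on the kept usage columns plus an intercept.

    Collinear designs are repaired by dropping columns in order of worst
    screen p until full rank (dropped genes are recorded).
    """
    common = strengths.index.intersection(usage.index)
    usage = usage.loc[common]
    c = strengths.loc[common].astype(float)
    screen = {}
    for gene in usage.columns:
        x = usage[gene].astype(float)
        if x.std(ddof=0) == 0 or c.std(ddof=0) == 0:
            continue
        screen[gene] = pearsonr(c, x)[1]
    screen = pd.Series(screen).sort_values()
    kept = list(screen.index[screen < alpha])
    if not kept:
        raise ClonoscopeError(
            "no TRAV gene passed the correlation screen "
            f"(alpha={alpha}); contraction may be constant or unrelated to usage"
        )
    dropped: list[str] = []
    X = sm.add_constant(usage[kept].astype(float))
    while np.linalg.matrix_rank(X.values) < X.shape[1]:
        dropped.append(kept.pop())  # worst screen p goes first
        if not kept:
            raise ClonoscopeError("all screened TRAV columns were collinear; no model fit")
        X = sm.add_constant(usage[kept].astype(float))
    fit = sm.OLS(c, X).fit()
    params = fit.params
    return TravModel(
        genes=kept,
        coefficients=params.drop("const"),
        intercept=float(params["const"]),
        coef_pvalues=fit.pvalues.drop("const"),
        predictions=pd.Series(fit.fittedvalues, index=common),
        screen_pvalues=screen,
        dropped_collinear=dropped,
    )


def predict_contraction_from_reference(
    study: list[ClonotypeRecord],
    reference: list[ClonotypeRecord],
    chain: str = "alpha",
    params: TcrDistParams | None = None,
) -> pd.Series:
    """Predict contraction from sequence proximity to reference contracting
    clonotypes (e.g. a published set of post-infection contracting clones).

    The neighborhood radius is the mean of all within-study pairwise
    single-chain distances; each study clonotype counts reference clonotypes
    strictly inside that radius, and the counts are min-max scaled to [0, 1]
    (all zero when counts are constant).
    """
    if not study or not reference:
        raise ClonoscopeError("study and reference clonotype sets must both be nonempty")
    if len(study) < 2:
        raise ClonoscopeError("need at least 2 study clonotypes to define the mean distance")
    params = params or TcrDistParams(chains=(chain,))
    if set(params.chains) != {chain}:
        params = TcrDistParams(
            mode=params.mode, chains=(chain,), cdr3_weight=params.cdr3_weight,
            loop_weight=params.loop_weight, trim_n=params.trim_n, trim_c=params.trim_c,
            gap_penalty=params.gap_penalty,
        )
    within = compute_tcrdist(study, params=params).values
    n = len(study)
    d_bar = within[np.triu_indices(n, k=1)].mean()
    cross = compute_tcrdist(study, reference, params=params).values
    neighbor_counts = (cross < d_bar).sum(axis=1)
    lo, hi = neighbor_counts.min(), neighbor_counts.max()
    if hi == lo:
        scaled = np.zeros(n)
    else:
        scaled = (neighbor_counts - lo) / (hi - lo)
    return pd.Series(scaled, index=[r.clonotype_id for r in study], name="predicted_contraction")


@dataclass
class SurvivalSplit:
    """Kaplan-Meier curves per score arm plus a 2x2 chi-square test."""

    curves: dict[str, pd.DataFrame]
    table: pd.DataFrame
    chi2: float
    p: float
    df: int = 1


def survival_split_test(
    patient_scores: pd.Series,
    threshold: float,
    survival: pd.DataFrame,
) -> SurvivalSplit:
    """Split patients at a score threshold and compare overall survival.

    ``survival`` needs columns patient_id, time, event (1 = death).  Each arm
    gets a product-limit (Kaplan-Meier) estimate; the test is a 1-df
    chi-square (no continuity correction) on the 2x2 contingency of survival
    outcome by score group.
    """
    from lifelines import KaplanMeierFitter

    surv = survival.set_index("patient_id").loc[patient_scores.index]
    groups = {"high": patient_scores >= threshold, "low": patient_scores < threshold}
    for name, mask in groups.items():
        if mask.sum() < 2:
            raise ClonoscopeError(f"arm {name!r} has fewer than 2 patients")
    curves = {}
    for name, mask in groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(surv.loc[mask.values, "time"], surv.loc[mask.values, "event"], label=name)
        curves[name] = kmf.survival_function_
    table = pd.DataFrame(
        {
            name: [
                int((surv.loc[mask.values, "event"] == 0).sum()),
                int((surv.loc[mask.values, "event"] == 1).sum()),
            ]
            for name, mask in groups.items()
        },
        index=["survived", "died"],
    )
    if table.values.sum(axis=1).min() == 0 or table.values.sum(axis=0).min() == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = chi2_contingency(table.values, correction=False)
    return SurvivalSplit(curves=curves, table=table, chi2=float(chi2), p=float(p))
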