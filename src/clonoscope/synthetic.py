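"""Synthetic antigen-specific CD8+ T cell cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes, with known ground truth at every level:

* clonotypes fall into sequence-similar clusters with cluster-specific V/J
  usage and CDR3 motifs (conserved anchor residues, divergent middles);
* each cluster carries a transcriptional program (cytotoxic / interferon /
  memory / naive); per-cell program activity is a weighted mix of the cluster
  loading, patient-level environment latents (plasma, HLA, dendritic cell)
  and per-cell noise;
* gene counts are negative-binomial with means exp-linear in program
  activity; surface-protein counts likewise, with a background antibody set;
* cell counts per clonotype contract from the acute draws (T1, T2) to
  convalescence (T3) according to a per-cluster target contraction profile;
* the environment blocks are low-rank-plus-noise matrices whose latents are
  exactly the factors mixed into the phenotype.

Effector (cytotoxic) program loading is coupled to the contraction target —
the more a cluster is set to contract, the more effector-like its cells —
mirroring the short-lived-effector biology the pipeline is meant to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError
from .records import AA_ALPHABET, ClonotypeRecord, write_airr
from .tcr_space import SIM_GERMLINE

PROGRAMS = ("cytotoxic", "interferon", "memory", "naive")
TIMEPOINTS = ("T1", "T2", "T3")

_TRAV_POOL = sorted((g for g in SIM_GERMLINE if g.startswith("TRAV")),
                    key=lambda g: int(g[4:-2]))
_TRBV_POOL = sorted((g for g in SIM_GERMLINE if g.startswith("TRBV")),
                    key=lambda g: int(g[4:-2]))
_TRAJ_POOL = [f"TRAJ{i}-S" for i in range(1, 11)]
_TRBJ_POOL = [f"TRBJ{i}-S" for i in range(1, 11)]


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort.

    ``effect_weights`` = (w_tcr, w_plasma, w_hla, w_cdc, w_noise) must be
    nonnegative and sum to 1; they set how strongly each factor shapes
    per-cell program activity.  ``contraction_profile`` gives each TCR
    cluster's target contraction strength in log10 units (negative =
    contraction); achievable targets are bounded below by
    -log10(mean acute % + 1), see the methods note.
    """

    n_patients: int = 12
    n_tcr_clusters: int = 4
    clonotypes_per_cluster: int = 25
    cells_per_clonotype_per_timepoint: float = 12.0
    n_genes: int = 300
    n_module_genes: int = 25
    n_proteins_plasma: int = 40
    n_surface_proteins: int = 12
    n_cdc_features: int = 30
    n_hla_alleles_pool: int = 30
    effect_weights: tuple[float, float, float, float, float] = (0.7, 0.1, 0.1, 0.1, 0.0)
    contraction_profile: tuple[float, ...] = (-1.0, -0.6, -0.3, 0.0)
    seed: int = 0
    # secondary shape parameters
    motif_divergence: float = 0.25
    cluster_chain_step: float = 0.35
    nb_dispersion: float = 0.5
    program_effect: float = 0.3
    contraction_coupling: float = 1.0
    background_fraction: float = 0.3
    n_batches: int = 2
    batch_effect: float = 0.0
    n_background_surface: int = 4

    def validate(self) -> None:
        counts = [
            "n_patients", "n_tcr_clusters", "clonotypes_per_cluster", "n_genes",
            "n_module_genes", "n_proteins_plasma", "n_surface_proteins",
            "n_cdc_features", "n_hla_alleles_pool", "n_batches",
        ]
        for name in counts:
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be at least 1")
        if self.cells_per_clonotype_per_timepoint <= 0:
            raise ConfigurationError("cells_per_clonotype_per_timepoint must be positive")
        w = np.asarray(self.effect_weights, dtype=float)
        if len(w) != 5 or (w < 0).any():
            raise ConfigurationError("effect_weights must be 5 nonnegative reals")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"effect_weights must sum to 1, got {w.sum()}")
        if len(self.contraction_profile) != self.n_tcr_clusters:
            raise ConfigurationError(
                "contraction_profile length must equal n_tcr_clusters "
                f"({len(self.contraction_profile)} != {self.n_tcr_clusters})"
            )
        if not 0 <= self.motif_divergence <= 1:
            raise ConfigurationError("motif_divergence must be in [0, 1]")
        if not 0 <= self.cluster_chain_step <= 1:
            raise ConfigurationError("cluster_chain_step must be in [0, 1]")
        if not 0 <= self.background_fraction < 1:
            raise ConfigurationError("background_fraction must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.n_module_genes * len(PROGRAMS) > self.n_genes:
            raise ConfigurationError(
                "n_module_genes x 4 programs exceeds n_genes"
            )
        if self.n_background_surface < 2 or self.n_background_surface > self.n_surface_proteins:
            raise ConfigurationError(
                "n_background_surface must be between 2 and n_surface_proteins"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_cluster: dict[str, int]
    cluster_programs: dict[int, str]
    loadings: pd.DataFrame
    consensus_cdr3: dict[int, tuple[str, str]]
    latents: dict[str, pd.DataFrame] = field(default_factory=dict)
    t3_multipliers: pd.Series | None = None
    realized_contraction: pd.Series | None = None

    def to_json(self) -> str:
        payload = {
            "true_cluster": self.true_cluster,
            "cluster_programs": {str(k): v for k, v in self.cluster_programs.items()},
            "loadings": self.loadings.to_dict(),
            "consensus_cdr3": {str(k): list(v) for k, v in self.consensus_cdr3.items()},
            "t3_multipliers": None if self.t3_multipliers is None else self.t3_multipliers.to_dict(),
            "realized_contraction": (
                None if self.realized_contraction is None
                else {str(k): v for k, v in self.realized_contraction.items()}
            ),
        }
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticCohort:
    """A fully generated cohort: clonotypes, cells, omic blocks, truth."""

    config: CohortConfig
    clonotypes: list[ClonotypeRecord]
    cells: ad.AnnData
    proteins: pd.DataFrame
    plasma: pd.DataFrame
    hla: pd.DataFrame
    cdc: pd.DataFrame
    totals: pd.DataFrame
    truth: GroundTruth

    def write(self, outdir) -> None:
        """Write the cohort to plain-text files (AIRR TSV, cell TSV,
        matrix-market counts, CSV omics, JSON ground truth)."""
        from scipy.io import mmwrite

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_airr(self.clonotypes, out / "clonotypes.tsv")
        self.cells.obs.to_csv(out / "cells.tsv", sep="\t")
        mmwrite(str(out / "gene_counts.mtx"), sp.csr_matrix(self.cells.X))
        (out / "genes.txt").write_text("\n".join(self.cells.var_names) + "\n")
        (out / "barcodes.txt").write_text("\n".join(self.cells.obs_names) + "\n")
        self.proteins.to_csv(out / "surface_proteins.csv")
        self.plasma.to_csv(out / "plasma.csv")
        self.hla.to_csv(out / "hla.csv")
        self.cdc.to_csv(out / "cdc.csv")
        self.totals.to_csv(out / "cd8_totals.csv", index=False)
        (out / "ground_truth.json").write_text(self.truth.to_json())


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def generate_clonotypes(config: CohortConfig) -> tuple[list[ClonotypeRecord], GroundTruth]:
    """Draw cluster-structured clonotypes with conserved CDR3 anchors.

    Each cluster prefers one V gene per chain (75% usage) and carries a
    consensus CDR3 per chain (length 10-18); members copy the consensus with
    the first/last 3 anchor residues fixed, middle positions mutated with
    probability ``motif_divergence`` and length jittered by +-1.
    Deterministic given the config seed.
    """
    config.validate()
    rng = _rng(config, 0)
    records: list[ClonotypeRecord] = []
    true_cluster: dict[str, int] = {}
    consensus: dict[int, tuple[str, str]] = {}
    cluster_programs = {c: PROGRAMS[c % 4] for c in range(config.n_tcr_clusters)}

    cons_a = cons_b = None
    for c in range(config.n_tcr_clusters):
        pref = {
            "va": _TRAV_POOL[c % len(_TRAV_POOL)],
            "vb": _TRBV_POOL[(c * 3 + 1) % len(_TRBV_POOL)],
            "ja": _TRAJ_POOL[c % len(_TRAJ_POOL)],
            "jb": _TRBJ_POOL[(c * 7 + 2) % len(_TRBJ_POOL)],
        }
        # consensus motifs form a mutation chain across clusters, giving the
        # sequence space a gradient (clusters have close and distant relatives)
        if cons_a is None:
            cons_a = _consensus_cdr3(rng)
            cons_b = _consensus_cdr3(rng)
        else:
            cons_a = _mutate_cdr3(rng, cons_a, config.cluster_chain_step)
            cons_b = _mutate_cdr3(rng, cons_b, config.cluster_chain_step)
        consensus[c] = (cons_a, cons_b)
        for i in range(config.clonotypes_per_cluster):
            cid = f"CT{c * config.clonotypes_per_cluster + i:05d}"
            # clusters span patients (public antigen-specific specificity groups);
            # balanced assignment keeps patient-level factors from proxying cluster
            rec = ClonotypeRecord(
                clonotype_id=cid,
                patient_id=f"P{(i + c) % config.n_patients:02d}",
                cdr3a=_mutate_cdr3(rng, cons_a, config.motif_divergence),
                cdr3b=_mutate_cdr3(rng, cons_b, config.motif_divergence),
                va=_pick_gene(rng, _TRAV_POOL, pref["va"]),
                ja=_pick_gene(rng, _TRAJ_POOL, pref["ja"]),
                vb=_pick_gene(rng, _TRBV_POOL, pref["vb"]),
                jb=_pick_gene(rng, _TRBJ_POOL, pref["jb"]),
                antigen="SIM-YLQ",
            )
            records.append(rec)
            true_cluster[cid] = c

    loadings = _program_loadings(config, cluster_programs)
    return records, GroundTruth(
        true_cluster=true_cluster,
        cluster_programs=cluster_programs,
        loadings=loadings,
        consensus_cdr3=consensus,
    )


def _consensus_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(10, 19))
    first = "C" + _random_seq(rng, 2)
    last = _random_seq(rng, 2) + "F"
    return first + _random_seq(rng, length - 6) + last


def _mutate_cdr3(rng: np.random.Generator, consensus: str, divergence: float) -> str:
    first, middle, last = consensus[:3], list(consensus[3:-3]), consensus[-3:]
    for i in range(len(middle)):
        if rng.random() < divergence:
            middle[i] = rng.choice(list(AA_ALPHABET))
    delta = int(rng.integers(-1, 2))
    target = int(np.clip(len(consensus) + delta, 10, 18))
    while len(middle) + 6 > target:
        middle.pop(len(middle) // 2)
    while len(middle) + 6 < target:
        middle.insert(len(middle) // 2, str(rng.choice(list(AA_ALPHABET))))
    return first + "".join(middle) + last


def _pick_gene(rng: np.random.Generator, pool: list[str], preferred: str, p: float = 0.75) -> str:
    if rng.random() < p:
        return preferred
    return str(rng.choice(pool))


def _program_loadings(config: CohortConfig, cluster_programs: dict[int, str]) -> pd.DataFrame:
    """Raw per-cluster loadings on the four programs.

    One-hot on the cluster's program, except the cytotoxic axis, which is
    graded by the (negated) contraction target: short-lived-effector clusters
    are the contracting ones.
    """
    L = pd.DataFrame(0.0, index=range(config.n_tcr_clusters), columns=list(PROGRAMS))
    for c, prog in cluster_programs.items():
        if prog != "cytotoxic":
            L.loc[c, prog] = 1.0
    L["cytotoxic"] = [
        config.contraction_coupling * (-t) for t in config.contraction_profile
    ]
    return L


def _standardize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    out = (df - mu).div(sd.replace(0.0, np.nan), axis=1).fillna(0.0)
    return out


def _solve_t3_multipliers(
    lam: np.ndarray,
    patient_idx: np.ndarray,
    cluster_idx: np.ndarray,
    background: np.ndarray,
    targets: np.ndarray,
    n_iter: int = 300,
) -> np.ndarray:
    """Per-cluster T3 count multipliers hitting the target contraction profile.

    Works on expected counts: acute mean percentages are computed from the
    baseline rates, the target convalescent percentages follow from the
    log10(%+1) contraction definition (clipped at zero where unreachable), and
    a proportional-fitting loop adjusts the multipliers, renormalizing the
    per-patient denominators each round.
    """
    n_clusters = len(targets)
    patients = np.unique(patient_idx)
    denom_a = np.array(
        [background[p] + lam[patient_idx == p].sum() for p in patients]
    )
    denom_of = {p: d for p, d in zip(patients, denom_a)}
    pct_a = 100.0 * lam / np.array([denom_of[p] for p in patient_idx])
    mean_a = np.array([pct_a[cluster_idx == c].mean() if (cluster_idx == c).any() else 0.0
                       for c in range(n_clusters)])
    target_v = np.maximum((mean_a + 1.0) * 10.0**targets - 1.0, 0.0)

    r = np.clip(10.0**targets, 1e-6, None)
    for _ in range(n_iter):
        scaled = lam * r[cluster_idx]
        denom_v = {
            p: background[p] + scaled[patient_idx == p].sum() for p in patients
        }
        pct_v = 100.0 * scaled / np.array([denom_v[p] for p in patient_idx])
        mean_v = np.array(
            [pct_v[cluster_idx == c].mean() if (cluster_idx == c).any() else 0.0
             for c in range(n_clusters)]
        )
        update = (target_v + 1e-9) / (mean_v + 1e-9)
        r = np.clip(r * update, 0.0, 1e3)
    return r


def generate_cells_and_omics(
    clonotypes: list[ClonotypeRecord],
    config: CohortConfig,
    truth: GroundTruth,
) -> SyntheticCohort:
    """Generate cells, expression/protein counts and environment omics.

    Per-cell program activity mixes the standardized cluster loading with
    standardized patient(-timepoint) environment latents and cell noise using
    ``effect_weights``; counts follow a negative binomial whose log-mean is
    linear in program activity.  Cell counts per clonotype per timepoint
    realize the contraction profile against a constant per-patient background
    CD8 pool (reported in ``totals`` but not instantiated as cells).
    """
    if not clonotypes:
        raise ConfigurationError("clonotypes must be nonempty")
    config.validate()
    rng = _rng(config, 1)
    w_tcr, w_plasma, w_hla, w_cdc, w_noise = config.effect_weights
    n_clusters = config.n_tcr_clusters

    ids = [r.clonotype_id for r in clonotypes]
    patient_names = sorted({r.patient_id for r in clonotypes})
    patient_of = {r.clonotype_id: r.patient_id for r in clonotypes}
    p_index = {p: i for i, p in enumerate(patient_names)}
    patient_idx = np.array([p_index[patient_of[i]] for i in ids])
    cluster_idx = np.array([truth.true_cluster[i] for i in ids])

    # ---- per-clonotype baseline rates and the T3 contraction multipliers
    lam = config.cells_per_clonotype_per_timepoint * rng.lognormal(0.0, 0.25, len(ids))
    f = config.background_fraction
    background = np.zeros(len(patient_names))
    for p, pi in p_index.items():
        background[pi] = np.round(f / (1 - f) * lam[patient_idx == pi].sum())
    r_mult = _solve_t3_multipliers(
        lam, patient_idx, cluster_idx, background, np.asarray(config.contraction_profile)
    )

    counts_per_tp = {
        "T1": rng.poisson(lam),
        "T2": rng.poisson(lam),
        "T3": rng.poisson(lam * r_mult[cluster_idx]),
    }

    # ---- environment latents (standardized across units)
    pt_units = [f"{p}|{t}" for p in patient_names for t in TIMEPOINTS]
    u_plasma = _standardize_columns(
        pd.DataFrame(rng.normal(size=(len(pt_units), 4)), index=pt_units, columns=PROGRAMS)
    )
    hla_freqs = rng.beta(2.0, 5.0, config.n_hla_alleles_pool)
    hla = pd.DataFrame(
        (rng.random((len(patient_names), config.n_hla_alleles_pool)) < hla_freqs).astype(int),
        index=patient_names,
        columns=[f"HLA-S{i:02d}" for i in range(config.n_hla_alleles_pool)],
    )
    G = rng.normal(size=(config.n_hla_alleles_pool, 4))
    v_hla = _standardize_columns(
        pd.DataFrame(hla.to_numpy(float) @ G, index=patient_names, columns=PROGRAMS)
    )
    c_cdc = _standardize_columns(
        pd.DataFrame(rng.normal(size=(len(patient_names), 4)), index=patient_names,
                     columns=PROGRAMS)
    )

    # ---- observable environment matrices (low-rank + noise; HLA is the table)
    n_prot = config.n_proteins_plasma
    Wp = np.zeros((4, n_prot))
    bounds = np.linspace(0, n_prot, 5).astype(int)
    for k in range(4):
        Wp[k, bounds[k]:bounds[k + 1]] = rng.normal(1.0, 0.2, bounds[k + 1] - bounds[k])
    plasma = pd.DataFrame(
        u_plasma.to_numpy() @ Wp + 0.5 * rng.normal(size=(len(pt_units), n_prot)),
        index=pt_units,
        columns=[f"PLASMA{j:03d}" for j in range(n_prot)],
    )
    cdc = pd.DataFrame(
        c_cdc.to_numpy() @ rng.normal(size=(4, config.n_cdc_features))
        + 0.5 * rng.normal(size=(len(patient_names), config.n_cdc_features)),
        index=patient_names,
        columns=[f"CDC{j:03d}" for j in range(config.n_cdc_features)],
    )

    # ---- cells and their program activities
    Ls = _standardize_columns(truth.loadings)
    rows = []
    for tp in TIMEPOINTS:
        for j, cid in enumerate(ids):
            for _ in range(int(counts_per_tp[tp][j])):
                rows.append((cid, patient_of[cid], tp))
    obs = pd.DataFrame(rows, columns=["clonotype_id", "patient_id", "timepoint"])
    obs.index = [f"CELL{i:06d}" for i in range(len(obs))]
    obs["batch"] = [
        f"B{p_index[p] % config.n_batches}" for p in obs["patient_id"]
    ]
    pt_key = obs["patient_id"] + "|" + obs["timepoint"]
    cell_cluster = obs["clonotype_id"].map(truth.true_cluster).to_numpy()

    activity = (
        w_tcr * Ls.to_numpy()[cell_cluster]
        + w_plasma * u_plasma.loc[pt_key].to_numpy()
        + w_hla * v_hla.loc[obs["patient_id"]].to_numpy()
        + w_cdc * c_cdc.loc[obs["patient_id"]].to_numpy()
        + w_noise * rng.normal(size=(len(obs), 4))
    )

    # ---- gene counts (negative binomial, log-mean linear in activity)
    n_cells = len(obs)
    gene_names = [f"G{j:04d}" for j in range(config.n_genes)]
    gene_program = np.full(config.n_genes, "none", dtype=object)
    M = np.zeros((config.n_genes, 4))
    for k, prog in enumerate(PROGRAMS):
        sl = slice(k * config.n_module_genes, (k + 1) * config.n_module_genes)
        gene_program[sl] = prog
        M[sl, k] = 1.0
    base = rng.normal(np.log(2.0), 0.3, config.n_genes)
    delta = rng.normal(0.0, config.batch_effect, (config.n_batches, config.n_genes))
    batch_idx = np.array([int(b[1:]) for b in obs["batch"]])
    log_mu = base[None, :] + config.program_effect * (activity @ M.T) + delta[batch_idx]
    libsize = rng.lognormal(0.0, 0.2, n_cells)
    mu = libsize[:, None] * np.exp(log_mu)
    shape = 1.0 / config.nb_dispersion
    gene_counts = rng.poisson(rng.gamma(shape, mu * config.nb_dispersion))

    cells = ad.AnnData(
        X=sp.csr_matrix(gene_counts),
        obs=obs,
        var=pd.DataFrame({"program": gene_program}, index=gene_names),
    )
    cells.obsm["program_activity"] = pd.DataFrame(
        activity, index=obs.index, columns=PROGRAMS
    )

    # ---- surface proteins (first n_background_surface are isotype-like)
    prot_names, prot_mu = [], []
    for j in range(config.n_surface_proteins):
        if j < config.n_background_surface:
            prot_names.append(f"BG{j}")
            prot_mu.append(np.full(n_cells, np.exp(0.7)))
        else:
            k = (j - config.n_background_surface) % 4
            prot_names.append(f"SP-{PROGRAMS[k][:3].upper()}{j}")
            prot_mu.append(np.exp(1.0 + 0.8 * activity[:, k]))
    proteins = pd.DataFrame(
        rng.poisson(np.column_stack(prot_mu)), index=obs.index, columns=prot_names
    )

    totals = pd.DataFrame(
        [
            {
                "patient_id": p,
                "timepoint": tp,
                "total_cells": int(background[p_index[p]])
                + int((pt_key == f"{p}|{tp}").sum()),
            }
            for p in patient_names
            for tp in TIMEPOINTS
        ]
    )

    truth.latents = {"plasma": u_plasma, "hla": v_hla, "cdc": c_cdc}
    truth.t3_multipliers = pd.Series(r_mult, index=range(n_clusters))

    cohort = SyntheticCohort(
        config=config,
        clonotypes=clonotypes,
        cells=cells,
        proteins=proteins,
        plasma=plasma,
        hla=hla,
        cdc=cdc,
        totals=totals,
        truth=truth,
    )
    truth.realized_contraction = _realized_contraction(cohort)
    return cohort


def _realized_contraction(cohort: SyntheticCohort) -> pd.Series:
    from .persistence import clonotype_frequencies, contraction_strength

    freq = clonotype_frequencies(cohort.cells.obs, totals=cohort.totals)
    labels = pd.Series(cohort.truth.true_cluster)
    table = contraction_strength(freq, labels)
    return table.strengths


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort (clonotypes, cells, omics) from one config."""
    config = config or CohortConfig()
    clonotypes, truth = generate_clonotypes(config)
    return generate_cells_and_omics(clonotypes, config, truth)


def planted_trav_cohort(
    n_clusters: int = 12,
    clonotypes_per_cluster: int = 10,
    slope: float = -0.01,
    intercept: float = -0.2,
    noise_sd: float = 0.05,
    gene: str = "TRAV1-S",
    seed: int = 0,
) -> tuple[list[ClonotypeRecord], pd.Series, pd.Series]:
    """Clusters with graded usage of one TRAV gene and contraction linear in
    that usage: C = slope * usage% + intercept + noise.

    Returns (clonotypes, cluster labels, contraction strengths) for exercising
    the TRAV regression.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    other = [g for g in _TRAV_POOL if g != gene]
    records: list[ClonotypeRecord] = []
    labels = {}
    strengths = {}
    for c in range(n_clusters):
        frac = c / max(n_clusters - 1, 1)
        n_gene = int(round(frac * clonotypes_per_cluster))
        usage_pct = 100.0 * n_gene / clonotypes_per_cluster
        strengths[c] = slope * usage_pct + intercept + rng.normal(0, noise_sd)
        for i in range(clonotypes_per_cluster):
            cid = f"PT{c:02d}_{i:02d}"
            records.append(
                ClonotypeRecord(
                    clonotype_id=cid,
                    patient_id="P00",
                    cdr3a="CAA" + _random_seq(rng, 6) + "QYF",
                    cdr3b="CAS" + _random_seq(rng, 6) + "QFF",
                    va=gene if i < n_gene else str(rng.choice(other)),
                    ja="TRAJ1-S",
                    vb="TRBV1-S",
                    jb="TRBJ1-S",
                )
            )
            labels[cid] = c
    return records, pd.Series(labels), pd.Series(strengths)
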