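"""Shared fixtures: memoized synthetic cohorts and their derived objects.

Several invariants are checked over the same seed sweep, so cohorts and the
expensive derived objects (distance matrix, graph, diffusion space, normalized
expression) are computed once per seed and shared across tests.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

import clonoscope as cs

warnings.filterwarnings("ignore", category=UserWarning)


@lru_cache(maxsize=16)
def default_run(seed: int):
    """Default 4-cluster cohort plus the standard TCR-space derivations."""
    cohort = cs.simulate_cohort(cs.CohortConfig(seed=seed))
    distances = cs.compute_tcrdist(cohort.clonotypes)
    graph = cs.build_graph(distances)
    space = cs.diffusion_components(graph)
    true_labels = pd.Series(cohort.truth.true_cluster)
    true_assignment = cs.ClusterAssignment(
        labels=true_labels.loc[distances.ids], resolution=0.0
    )
    norm = cs.normalize_log_cpm(cohort.cells)
    return {
        "cohort": cohort,
        "distances": distances,
        "graph": graph,
        "space": space,
        "true_assignment": true_assignment,
        "norm": norm,
    }


@lru_cache(maxsize=1)
def null_importance_tables() -> list[cs.ImportanceTable]:
    """Factor-importance tables under the global null (w_noise = 1), 100 seeds."""
    tables = []
    for seed in range(100):
        cfg = cs.CohortConfig(seed=seed, effect_weights=(0.0, 0.0, 0.0, 0.0, 1.0))
        tables.append(cs.importance_pipeline(cs.simulate_cohort(cfg), seed=seed))
    return tables


@lru_cache(maxsize=1)
def tcr_importance_tables() -> list[cs.ImportanceTable]:
    """Factor-importance tables with w_tcr = 0.7 and 0.1 per environment block."""
    tables = []
    for seed in range(20):
        cfg = cs.CohortConfig(seed=seed, effect_weights=(0.7, 0.1, 0.1, 0.1, 0.0))
        tables.append(cs.importance_pipeline(cs.simulate_cohort(cfg), seed=seed))
    return tables


@pytest.fixture(scope="session")
def null_tables():
    return null_importance_tables()


@pytest.fixture(scope="session")
def tcr_tables():
    return tcr_importance_tables()


@pytest.fixture()
def toy_clonotype():
    def make(cid="CT0", cdr3a="CAVSGGYQKVTF", cdr3b="CASSLGTDTQYF",
             va="TRAV1-S", ja="TRAJ1-S", vb="TRBV1-S", jb="TRBJ1-S", patient="P00"):
        return cs.ClonotypeRecord(
            clonotype_id=cid, patient_id=patient, cdr3a=cdr3a, cdr3b=cdr3b,
            va=va, ja=ja, vb=vb, jb=jb, antigen="SIM-YLQ",
        )

    return make


def random_clonotype(rng: np.random.Generator, cid: str, alphabet: str = cs.AA_ALPHABET):
    """A random valid clonotype with simulated gene names."""
    travs = [g for g in cs.tcr_space.SIM_GERMLINE if g.startswith("TRAV")]
    trbvs = [g for g in cs.tcr_space.SIM_GERMLINE if g.startswith("TRBV")]

    def seq():
        return "".join(rng.choice(list(alphabet), size=rng.integers(10, 19)))

    return cs.ClonotypeRecord(
        clonotype_id=cid, patient_id="P00", cdr3a=seq(), cdr3b=seq(),
        va=str(rng.choice(travs)), ja="TRAJ1-S", vb=str(rng.choice(trbvs)), jb="TRBJ1-S",
    )
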