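"""Normalization, marker genes, modules, signatures, CITE-seq and density."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import clonoscope as cs

from conftest import default_run
from oracles import brute_knn_diffusion


def _adata(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{j}" for j in range(counts.shape[1])]
    cells = cells or [f"C{i}" for i in range(counts.shape[0])]
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(float)),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame(index=genes),
    )


class TestNormalizeLogCpm:
    def test_zero_count_maps_to_zero_and_single_gene_cell_saturates(self):
        adata = _adata([[5, 0], [1, 1]])
        norm = cs.normalize_log_cpm(adata)
        x = norm.X.toarray()
        assert x[0, 1] == 0.0
        assert x[0, 0] == pytest.approx(np.log(1 + 1e6))

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(10, 6))
        counts[counts.sum(axis=1) == 0, 0] = 1
        norm = cs.normalize_log_cpm(_adata(counts)).X.toarray()
        for i in range(10):
            total = counts[i].sum()
            for j in range(6):
                assert norm[i, j] == pytest.approx(
                    np.log(1 + 1e6 * counts[i, j] / total), abs=1e-10
                )

    def test_matches_scanpy_normalization(self):
        scanpy = pytest.importorskip("scanpy")
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 30, size=(20, 8))
        ours = cs.normalize_log_cpm(_adata(counts)).X.toarray()
        other = _adata(counts)
        scanpy.pp.normalize_total(other, target_sum=1e6)
        scanpy.pp.log1p(other)
        assert np.allclose(ours, other.X.toarray(), atol=1e-8)

    def test_preserves_within_cell_rank_order(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 50, size=(5, 12))
        counts[:, 0] += 1
        norm = cs.normalize_log_cpm(_adata(counts)).X.toarray()
        for i in range(5):
            for j, k in itertools.combinations(range(12), 2):
                assert np.sign(counts[i, j] - counts[i, k]) == np.sign(
                    norm[i, j] - norm[i, k]
                )

    def test_zero_total_cells_are_excluded_with_warning(self):
        adata = _adata([[1, 2], [0, 0], [3, 4]])
        with pytest.warns(UserWarning, match="zero-count"):
            norm = cs.normalize_log_cpm(adata)
        assert norm.n_obs == 2


class TestRankMarkerGenes:
    def test_toy_two_group_case_reproduces_exact_enumerated_p(self):
        """Values 1,2,3 vs 10,11,12: U = 0 and the exact permutation p."""
        counts = np.array([[1], [2], [3], [10], [11], [12]])
        adata = _adata(counts)
        labels = ["a", "a", "a", "b", "b", "b"]
        tables = cs.rank_marker_genes(adata, labels)
        row = tables["a"].iloc[0]
        assert row["U"] == 0.0
        # oracle: enumerate all C(6,3) group assignments of the pooled values
        values = counts.ravel().astype(float)
        extreme = 0
        combos = list(itertools.combinations(range(6), 3))
        u_obs = min(
            sum(1 for i in (0, 1, 2) for j in (3, 4, 5) if values[i] > values[j]),
            sum(1 for j in (3, 4, 5) for i in (0, 1, 2) if values[j] > values[i]),
        )
        for combo in combos:
            rest = [i for i in range(6) if i not in combo]
            u = sum(1 for i in combo for j in rest if values[i] > values[j])
            u = min(u, 9 - u)
            if u <= u_obs:
                extreme += 1
        assert row["p"] == pytest.approx(extreme / len(combos))

    def test_constant_gene_gets_p_one(self):
        counts = np.array([[1, 7], [2, 7], [3, 7], [10, 7], [11, 7], [12, 7]])
        tables = cs.rank_marker_genes(_adata(counts), ["a"] * 3 + ["b"] * 3)
        const = tables["a"].set_index("gene").loc["G1"]
        assert const["p"] == 1.0

    def test_pvalues_invariant_to_monotone_gene_transform(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 40, size=(12, 5))
        labels = ["a"] * 6 + ["b"] * 6
        base = cs.rank_marker_genes(_adata(counts), labels)
        squared = cs.rank_marker_genes(_adata(counts**2), labels)
        # the rank test only sees orderings, which squaring preserves
        for lab in ("a", "b"):
            a = base[lab].set_index("gene")["p"]
            b = squared[lab].set_index("gene")["p"]
            assert np.allclose(a.sort_index(), b.sort_index())

    def test_label_permutation_permutes_top_genes(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 30, size=(20, 10))
        counts[:10, 0] += 50  # marker for first half
        labels = np.array(["a"] * 10 + ["b"] * 10)
        t1 = cs.rank_marker_genes(_adata(counts), labels)
        t2 = cs.rank_marker_genes(_adata(counts), np.where(labels == "a", "b", "a"))
        assert t1["a"].iloc[0]["gene"] == t2["b"].iloc[0]["gene"]

    def test_degenerate_label_sizes_raise(self):
        counts = np.ones((4, 2))
        with pytest.raises(cs.ClonoscopeError, match="fewer than 3"):
            cs.rank_marker_genes(_adata(counts), ["a", "a", "a", "b"])


class TestDiscoverModules:
    def _planted_adata(self, seed=0, n_cells=60):
        """Two perfectly anti-correlated 4-gene blocks."""
        rng = np.random.default_rng(seed)
        f = rng.normal(size=n_cells)
        X = np.column_stack([f, f * 2, f + 1, f * 3 - 1, -f, -f * 2, -f + 2, -f * 0.5])
        adata = ad.AnnData(
            X=X, obs=pd.DataFrame(index=[f"C{i}" for i in range(n_cells)]),
            var=pd.DataFrame(index=[f"G{j}" for j in range(8)]),
        )
        degs = {
            "x": pd.DataFrame({"gene": [f"G{j}" for j in range(8)]}),
        }
        return adata, degs

    def test_planted_anticorrelated_blocks_recovered_exactly(self):
        adata, degs = self._planted_adata()
        mods = cs.discover_modules(adata, degs, top_n=8, k_range=range(2, 4))
        assert mods.k == 2
        sets = sorted(frozenset(v) for v in mods.modules.values())
        assert sets == sorted(
            [frozenset({"G0", "G1", "G2", "G3"}), frozenset({"G4", "G5", "G6", "G7"})]
        )

    def test_perfectly_correlated_genes_fall_back_to_smallest_k(self):
        rng = np.random.default_rng(1)
        f = rng.normal(size=40)
        X = np.column_stack([f * s + o for s, o in [(1, 0), (2, 1), (3, -1), (0.5, 2), (4, 0)]])
        adata = ad.AnnData(
            X=X, obs=pd.DataFrame(index=[f"C{i}" for i in range(40)]),
            var=pd.DataFrame(index=[f"G{j}" for j in range(5)]),
        )
        degs = {"x": pd.DataFrame({"gene": [f"G{j}" for j in range(5)]})}
        with pytest.warns(UserWarning, match="degenerate|silhouette"):
            mods = cs.discover_modules(adata, degs, top_n=5, k_range=range(2, 4))
        assert mods.k <= 2

    def test_invariant_to_gene_order_permutation(self):
        adata, _ = self._planted_adata(seed=2)
        order = [3, 6, 1, 7, 0, 5, 2, 4]
        degs1 = {"x": pd.DataFrame({"gene": [f"G{j}" for j in range(8)]})}
        degs2 = {"x": pd.DataFrame({"gene": [f"G{j}" for j in order]})}
        m1 = cs.discover_modules(adata, degs1, top_n=8, k_range=range(2, 4))
        m2 = cs.discover_modules(adata, degs2, top_n=8, k_range=range(2, 4))
        assert sorted(frozenset(v) for v in m1.modules.values()) == sorted(
            frozenset(v) for v in m2.modules.values()
        )

    def test_constant_gene_dropped_with_warning(self):
        adata, _ = self._planted_adata(seed=3)
        adata.X[:, 0] = 5.0
        degs = {"x": pd.DataFrame({"gene": [f"G{j}" for j in range(8)]})}
        with pytest.warns(UserWarning, match="constant"):
            mods = cs.discover_modules(adata, degs, top_n=8, k_range=range(2, 4))
        assert "G0" not in mods.gene_to_module


class TestScoreSignature:
    def test_single_gene_signature_equals_that_gene(self):
        run = default_run(0)
        norm = run["norm"]
        s = cs.score_signature(norm, ["G0000"])
        assert np.allclose(s.values, norm[:, "G0000"].X.toarray().ravel())

    def test_uniform_cell_scores_the_common_value(self):
        adata = _adata(np.full((3, 4), 7))
        norm = cs.normalize_log_cpm(adata)
        s = cs.score_signature(norm, [f"G{j}" for j in range(4)])
        assert np.allclose(s.values, np.log(1 + 1e6 / 4))

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 20, size=(6, 5))
        norm = cs.normalize_log_cpm(_adata(counts))
        genes = ["G1", "G3", "G4"]
        s = cs.score_signature(norm, genes)
        X = norm.X.toarray()
        for i in range(6):
            assert s.iloc[i] == pytest.approx(np.mean([X[i, 1], X[i, 3], X[i, 4]]), abs=1e-10)

    def test_missing_genes_warn_and_all_missing_raises(self):
        norm = cs.normalize_log_cpm(_adata(np.ones((3, 2))))
        with pytest.warns(UserWarning, match="missing"):
            cs.score_signature(norm, ["G0", "NOPE"])
        with pytest.raises(cs.ClonoscopeError, match="none"):
            cs.score_signature(norm, ["NOPE"])


class TestBatchStandardize:
    def test_single_batch_equals_global_zscore(self):
        rng = np.random.default_rng(0)
        sigs = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        out = cs.batch_standardize_signatures(sigs, np.zeros(30))
        expected = (sigs - sigs.mean()) / sigs.std(ddof=0)
        assert np.allclose(out.values, expected.values, atol=1e-10)

    def test_shifted_batches_end_with_equal_means(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 2))
        sigs = pd.DataFrame(np.vstack([base[:20] + 5, base[20:]]))
        batches = np.array([0] * 20 + [1] * 20)
        out = cs.batch_standardize_signatures(sigs, batches)
        m0 = out[batches == 0].mean()
        m1 = out[batches == 1].mean()
        assert np.allclose(m0, m1, atol=1e-10)

    def test_singleton_batch_left_uncentered_with_warning(self):
        sigs = pd.DataFrame(np.arange(10.0).reshape(5, 2))
        with pytest.warns(UserWarning, match="single"):
            out = cs.batch_standardize_signatures(sigs, [0, 0, 0, 0, 1])
        assert np.allclose(out.iloc[4].values, sigs.iloc[4].values)

    def test_batch_effect_silhouette_drops_after_correction(self):
        from sklearn.metrics import silhouette_score

        drops = []
        for seed in range(10):
            cfg = cs.CohortConfig(
                seed=seed, clonotypes_per_cluster=8,
                cells_per_clonotype_per_timepoint=5.0, batch_effect=1.5,
            )
            cohort = cs.simulate_cohort(cfg)
            norm = cs.normalize_log_cpm(cohort.cells)
            var = cohort.cells.var
            sigs = pd.DataFrame(
                {
                    prog: cs.score_signature(norm, list(var.index[var["program"] == prog]))
                    for prog in cs.PROGRAMS
                }
            )
            batches = norm.obs["batch"].values
            corrected = cs.batch_standardize_signatures(sigs, batches)
            before = silhouette_score(sigs.values, batches)
            after = silhouette_score(corrected.values, batches)
            drops.append(after < before)
        assert np.mean(drops) >= 0.9


class TestSurfaceProteins:
    def test_protein_at_background_mean_gets_zero_z(self):
        counts = pd.DataFrame(
            {"BG1": [3, 5], "BG2": [5, 9], "P": [4, 7]}, index=["c1", "c2"]
        )
        z, flagged = cs.normalize_surface_proteins(counts, ["BG1", "BG2"])
        # ln(1+4) is the mean of ln(1+3), ln(1+5)? not exactly; build exact case
        logc = np.log1p(counts)
        expected = (logc["P"] - logc[["BG1", "BG2"]].mean(axis=1)) / logc[
            ["BG1", "BG2"]
        ].std(axis=1, ddof=0)
        assert np.allclose(z["P"].values, expected.values)
        assert len(flagged) == 0

    def test_equal_background_counts_flag_the_cell(self):
        counts = pd.DataFrame({"BG1": [4, 3], "BG2": [4, 5], "P": [9, 9]})
        with pytest.warns(UserWarning, match="flagged"):
            z, flagged = cs.normalize_surface_proteins(counts, ["BG1", "BG2"])
        assert list(flagged) == [0]
        assert (z.loc[0] == 0).all()

    def test_fewer_than_two_background_proteins_raises(self):
        counts = pd.DataFrame({"BG1": [4], "P": [9]})
        with pytest.raises(cs.ClonoscopeError, match="background"):
            cs.normalize_surface_proteins(counts, ["BG1"])

    def test_effector_linked_protein_peaks_in_the_effector_cluster(self):
        run = default_run(0)
        cohort = run["cohort"]
        bg = [c for c in cohort.proteins.columns if c.startswith("BG")]
        z, _ = cs.normalize_surface_proteins(cohort.proteins, bg)
        cyt_protein = next(c for c in cohort.proteins.columns if c.startswith("SP-CYT"))
        labels = cohort.cells.obs["clonotype_id"].map(cohort.truth.true_cluster)
        means = z[cyt_protein].groupby(labels.values).mean()
        assert means.idxmax() == 0  # cluster 0 carries the top effector loading


class TestDensityDiffusion:
    def test_uniform_members_on_a_ring_stay_constant(self):
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        coords = np.column_stack([np.cos(theta), np.sin(theta)])
        density = cs.diffuse_embedding_density(coords, np.ones(24, dtype=bool), k=2)
        assert np.allclose(density, density[0], atol=1e-8)

    def test_single_corner_member_matches_matrix_power_oracle(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.normal(0, 1, size=(30, 2)), [[8.0, 8.0]]])
        members = np.zeros(31, dtype=bool)
        members[30] = True
        density = cs.diffuse_embedding_density(coords, members, k=5, iterations=5)
        # oracle: same kernel/minmax then explicit 5-step matrix power
        mem = coords[members]
        h = coords.std(axis=0, ddof=0) * 31 ** (-1 / 6)
        raw = np.exp(-0.5 * (((coords - mem[0]) / h) ** 2).sum(axis=1))
        scaled = (raw - raw.min()) / (raw.max() - raw.min())
        expected = brute_knn_diffusion(coords, scaled, k=5, iterations=5)
        assert np.allclose(density, expected, atol=1e-10)
        # before diffusion the kernel peaks at the member and decays with distance
        undiffused = cs.diffuse_embedding_density(coords, members, k=5, iterations=0)
        assert undiffused.argmax() == 30
        dist_to_member = np.linalg.norm(coords - coords[30], axis=1)
        order = np.argsort(dist_to_member)
        assert (np.diff(undiffused[order]) <= 1e-12).all()

    def test_total_mass_is_conserved(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(50, 2))
        members = rng.random(50) < 0.3
        density = cs.diffuse_embedding_density(coords, members, k=5, iterations=0)
        diffused = cs.diffuse_embedding_density(coords, members, k=5, iterations=5)
        assert diffused.sum() == pytest.approx(density.sum(), abs=1e-8)

    def test_no_members_returns_zero_vector_with_warning(self):
        coords = np.random.default_rng(2).normal(size=(10, 2))
        with pytest.warns(UserWarning, match="no member"):
            density = cs.diffuse_embedding_density(coords, np.zeros(10, dtype=bool))
        assert np.allclose(density, 0.0)
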