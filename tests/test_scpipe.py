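"""Single-cell stage: gating, QC, clustering, pseudobulk NB-QL DE."""

import numpy as np
import pandas as pd
import pytest
import anndata as ad

from mircell import scpipe, synthio


def _adata(X, donors=None, groups=None, mito=None, genes=None):
    n, g = X.shape
    genes = genes or [f"g{i}" for i in range(g)]
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs["donor"] = donors if donors is not None else "d1"
    obs["group"] = groups if groups is not None else "case"
    var = pd.DataFrame(index=genes)
    var["mito"] = mito if mito is not None else False
    return ad.AnnData(X=np.asarray(X), obs=obs, var=var)


class TestGating:
    def test_gating_rules(self):
        X = np.array([
            [1, 2, 0],   # CD3G+ CD8A+ -> kept
            [0, 5, 0],   # CD3G- -> removed
            [1, 0, 1],   # CD3G+ CD8B+ -> kept
            [1, 0, 0],   # CD3G+ CD8- -> removed
        ])
        a = _adata(X, genes=["CD3G", "CD8A", "CD8B"])
        out = scpipe.gate_cd8(a)
        assert list(out.obs_names) == ["c0", "c2"]
        assert out.uns["gate_cd8"] == {"n_in": 4, "n_kept": 2}

    def test_missing_gene_raises(self):
        a = _adata(np.ones((3, 2)), genes=["CD3G", "CD8A"])
        with pytest.raises(ValueError, match="CD8B"):
            scpipe.gate_cd8(a)


class TestQC:
    def test_homogeneous_cells_untouched(self, rng):
        X = rng.poisson(5, (50, 30))
        a = _adata(X, mito=[True] * 3 + [False] * 27)
        out = scpipe.qc_filter(a, nmads=3)
        assert out.n_obs == 50

    def test_mito_outlier_flagged(self, rng):
        X = rng.poisson(10, (40, 20)).astype(float)
        mito = [True] * 2 + [False] * 18
        # typical cells ~5% mito; one cell at ~40%
        X[:, :2] = rng.poisson(1, (40, 2))
        X[0, :2] = 60
        a = _adata(X, mito=mito)
        out = scpipe.qc_filter(a, nmads=3)
        assert "c0" not in out.obs_names
        assert out.uns["qc_filter"]["high_mito"] >= 1

    def test_infinite_nmads_identity(self, rng):
        X = rng.poisson(5, (30, 10))
        a = _adata(X, mito=[False] * 10)
        assert scpipe.qc_filter(a, nmads=np.inf).n_obs == 30

    def test_conservation_of_cell_counts(self):
        cfg = synthio.SimConfig(seed=3, n_donors=2, cells_per_donor=100)
        a, _ = synthio.simulate_single_cell(cfg)
        gated = scpipe.gate_cd8(a)
        qced = scpipe.qc_filter(gated)
        removed_gate = a.n_obs - gated.uns["gate_cd8"]["n_kept"]
        removed_qc = qced.uns["qc_filter"]["n_removed"]
        assert removed_gate + removed_qc + qced.n_obs == a.n_obs


class TestNormalize:
    def test_equal_totals_identity_scaling(self):
        X = np.array([[1, 3], [2, 2], [3, 1]], dtype=float)
        a = _adata(X)
        scpipe.normalize_log(a)
        assert np.allclose(a.layers["lognorm"], np.log2(X + 1))

    def test_depth_invariance(self):
        X = np.array([[1.0, 3, 6], [2.0, 6, 12]])
        a = _adata(X)
        scpipe.normalize_log(a)
        assert np.allclose(a.layers["lognorm"][0], a.layers["lognorm"][1])

    def test_zero_maps_to_zero_and_zero_cell_rejected(self):
        a = _adata(np.array([[0.0, 5], [5.0, 0]]))
        scpipe.normalize_log(a)
        assert a.layers["lognorm"][0, 0] == 0.0
        bad = _adata(np.array([[0.0, 0], [5.0, 1]]))
        with pytest.raises(ValueError):
            scpipe.normalize_log(bad)


class TestHVG:
    def test_planted_bimodal_gene_ranks_top(self, rng):
        n = 200
        rates = rng.uniform(1, 10, 50)  # spread of means supports the trend
        X = rng.poisson(rates[None, :] * np.ones((n, 1))).astype(float)
        X[:40, 0] = rng.poisson(rates[0] * 8, 40)  # bimodal subpopulation
        a = _adata(X)
        scpipe.normalize_log(a)
        hvgs = scpipe.select_hvgs(a, n=10)
        assert "g0" in hvgs

    def test_all_genes_when_n_equals_total(self, rng):
        a = _adata(rng.poisson(3, (30, 10)) + 1)
        scpipe.normalize_log(a)
        assert set(scpipe.select_hvgs(a, n=10)) == set(a.var_names)
        with pytest.raises(ValueError):
            scpipe.select_hvgs(a, n=11)


class TestBatchCorrection:
    def _two_batches(self, rng, shift):
        n, g = 120, 30
        base = rng.normal(2, 1, (n, g))
        x2 = rng.normal(2, 1, (n, g)) + shift
        X = np.vstack([base, x2])
        a = _adata(np.round(np.exp2(np.abs(X))).astype(int),
                   donors=["d1"] * n + ["d2"] * n,
                   groups=["case"] * n + ["control"] * n)
        a.layers["lognorm"] = X
        return a

    def test_null_batches_correction_small(self, rng):
        a = self._two_batches(rng, shift=0.0)
        emb = scpipe.correct_batch(a, batch_key="donor", n_pcs=10, k=20, seed=0)
        from sklearn.decomposition import PCA
        emb0 = PCA(10, random_state=0).fit_transform(a.layers["lognorm"])
        scale = np.linalg.norm(emb0.std(axis=0))
        moved = np.linalg.norm(emb - emb0, axis=1).mean()
        assert moved < 0.5 * scale

    def test_planted_shift_reduced(self, rng):
        a = self._two_batches(rng, shift=3.0)
        emb = scpipe.correct_batch(a, batch_key="donor", n_pcs=10, k=20, seed=0)
        from sklearn.decomposition import PCA
        emb0 = PCA(10, random_state=0).fit_transform(a.layers["lognorm"])
        n = 120
        d_before = np.linalg.norm(emb0[:n].mean(0) - emb0[n:].mean(0))
        d_after = np.linalg.norm(emb[:n].mean(0) - emb[n:].mean(0))
        assert d_after <= 0.2 * d_before

    def test_single_batch_identity(self, rng):
        n, g = 50, 20
        X = rng.normal(2, 1, (n, g))
        a = _adata(np.ones((n, g)), donors=["d1"] * n)
        a.layers["lognorm"] = X
        emb = scpipe.correct_batch(a, batch_key="donor", n_pcs=5, k=10, seed=0)
        from sklearn.decomposition import PCA
        assert np.allclose(emb, PCA(5, random_state=0).fit_transform(X))

    def test_small_batch_rejected(self, rng):
        a = self._two_batches(rng, 0.0)
        with pytest.raises(ValueError, match="fewer than k"):
            scpipe.correct_batch(a, batch_key="donor", k=200)


class TestClustering:
    def test_separated_blobs_recovered(self, rng):
        emb = np.vstack([rng.normal(0, 0.1, (50, 3)),
                         rng.normal(5, 0.1, (50, 3))])
        labels = scpipe.snn_louvain(emb, k=10, seed=0, resolution=0.1)
        assert len(set(labels)) == 2
        assert len(set(labels[:50])) == 1
        assert len(set(labels[50:])) == 1

    def test_deterministic_under_fixed_seed(self, rng):
        emb = rng.normal(size=(80, 4))
        l1 = scpipe.snn_louvain(emb, k=5, seed=3)
        l2 = scpipe.snn_louvain(emb, k=5, seed=3)
        assert np.array_equal(l1, l2)

    def test_labels_ordered_by_size(self, rng):
        emb = np.vstack([rng.normal(0, 0.1, (60, 2)),
                         rng.normal(8, 0.1, (20, 2))])
        labels = scpipe.snn_louvain(emb, k=8, seed=0, resolution=0.1)
        counts = pd.Series(labels).value_counts()
        assert counts.index[0] == 0  # biggest cluster gets label 0

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            scpipe.snn_louvain(rng.normal(size=(5, 2)), k=5)


class TestLabelTransfer:
    def test_exact_profile_match(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ref = pd.DataFrame(
            {"typeA": rng.normal(5, 2, 60), "typeB": rng.normal(5, 2, 60)},
            index=genes,
        )
        a = _adata(np.ones((2, 60)), genes=genes)
        a.layers["lognorm"] = np.vstack([ref["typeA"], ref["typeB"]])
        out = scpipe.label_transfer(a, ref)
        assert list(out["label"]) == ["typeA", "typeB"]
        assert np.allclose(out["score"], 1.0)

    def test_gene_order_permutation_invariance(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ref = pd.DataFrame(
            {"A": rng.normal(size=60), "B": rng.normal(size=60)}, index=genes
        )
        L = rng.normal(size=(5, 60))
        a = _adata(np.ones((5, 60)), genes=genes)
        a.layers["lognorm"] = L
        out1 = scpipe.label_transfer(a, ref)
        out2 = scpipe.label_transfer(a, ref.sample(frac=1, random_state=0))
        assert list(out1["label"]) == list(out2["label"])

    def test_insufficient_overlap_rejected(self, rng):
        ref = pd.DataFrame({"A": [1.0, 2], "B": [2.0, 1]}, index=["g0", "g1"])
        a = _adata(np.ones((2, 60)))
        a.layers["lognorm"] = rng.normal(size=(2, 60))
        with pytest.raises(ValueError, match="overlap"):
            scpipe.label_transfer(a, ref)


class TestScoreMarkers:
    def test_exclusive_gene_auc_one(self):
        L = np.zeros((10, 2))
        L[:5, 0] = 5.0  # g0 expressed only in cluster 0
        a = _adata(np.ones((10, 2)))
        a.layers["lognorm"] = L
        auc = scpipe.score_markers(a, np.array([0] * 5 + [1] * 5))
        assert auc.loc["g0", 0] == pytest.approx(1.0)
        assert auc.loc["g1", 0] == pytest.approx(0.5)  # identical everywhere

    def test_matches_bruteforce_pair_counting(self, rng):
        L = rng.normal(size=(18, 5))
        L[rng.random((18, 5)) < 0.3] = 0.0  # inject ties
        labels = np.array([0] * 6 + [1] * 5 + [2] * 7)
        a = _adata(np.ones((18, 5)))
        a.layers["lognorm"] = L
        auc = scpipe.score_markers(a, labels)

        def brute(gi, A, B):
            wins = sum(
                1.0 if L[i, gi] > L[j, gi] else 0.5 if L[i, gi] == L[j, gi] else 0.0
                for i in A for j in B
            )
            return wins / (len(A) * len(B))

        idx = {u: [i for i in range(18) if labels[i] == u] for u in (0, 1, 2)}
        for u in (0, 1, 2):
            others = [v for v in (0, 1, 2) if v != u]
            for gi in range(5):
                expected = np.mean([brute(gi, idx[u], idx[v]) for v in others])
                assert auc.iloc[gi][u] == pytest.approx(expected, abs=1e-12)


class TestPseudobulk:
    def test_sums_and_conservation(self):
        X = np.array([[1, 3], [2, 4], [5, 0]])
        a = _adata(X, donors=["d1", "d1", "d2"], groups=["case", "case", "control"])
        pb = scpipe.pseudobulk(a, min_cells=1)
        assert np.array_equal(pb.counts["d1"], [3, 7])
        assert pb.counts.to_numpy().sum() == X.sum()
        assert pb.groups["d1"] == "case"

    def test_small_donor_dropped_with_warning(self):
        X = np.ones((5, 2))
        a = _adata(X, donors=["d1"] * 4 + ["d2"],
                   groups=["case"] * 4 + ["control"])
        with pytest.warns(UserWarning, match="d2"):
            pb = scpipe.pseudobulk(a, min_cells=2)
        assert list(pb.counts.columns) == ["d1"]

    def test_mixed_group_donor_rejected(self):
        a = _adata(np.ones((2, 2)), donors=["d1", "d1"],
                   groups=["case", "control"])
        with pytest.raises(ValueError, match="mixed"):
            scpipe.pseudobulk(a, min_cells=1)


class TestTMM:
    def _pb(self, Y, groups=None):
        cols = [f"d{i}" for i in range(Y.shape[1])]
        groups = groups or ["case"] * (Y.shape[1] // 2) + ["control"] * (
            Y.shape[1] - Y.shape[1] // 2
        )
        return scpipe.Pseudobulk(
            counts=pd.DataFrame(Y, index=[f"g{i}" for i in range(Y.shape[0])],
                                columns=cols),
            groups=pd.Series(groups, index=cols),
        )

    def test_identical_columns_unit_factors(self, rng):
        col = rng.poisson(50, 200)
        pb = self._pb(np.column_stack([col] * 4))
        assert np.allclose(scpipe.tmm_factors(pb), 1.0)

    def test_depth_absorbed_by_library_size(self, rng):
        col = rng.poisson(50, 300) + 1
        pb = self._pb(np.column_stack([col, 2 * col, col]))
        assert np.allclose(scpipe.tmm_factors(pb), 1.0, atol=1e-9)

    def test_geometric_mean_one(self, rng):
        Y = rng.negative_binomial(5, 0.1, (300, 6))
        f = scpipe.tmm_factors(self._pb(Y))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.skipif(
        __import__("shutil").which("Rscript") is None, reason="Rscript unavailable"
    )
    def test_matches_edger_reference(self, rng, tmp_path):
        import json
        import subprocess

        mu = np.exp(rng.normal(np.log(50), 1, (300, 1)))
        Y = rng.negative_binomial(5, 5 / (5 + mu * np.ones((1, 6))))
        Y = np.round(Y * np.array([1, 2, 0.5, 1, 1.5, 0.8])[None, :]).astype(int)
        pb = self._pb(Y)
        path = tmp_path / "y.tsv"
        pb.counts.to_csv(path, sep="\t")
        script = f'''
suppressMessages(library(edgeR))
y <- as.matrix(read.delim("{path}", row.names=1))
cat(jsonlite::toJSON(calcNormFactors(y, method="TMM")))
'''
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array(json.loads(out.stdout))
        assert np.allclose(scpipe.tmm_factors(pb), ref, rtol=1e-3)


class TestNBQL:
    def _null_pb(self, seed, n_genes=400, n=12):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.normal(np.log(100), 1.5, n_genes))
        lib = np.exp(rng.normal(0, 0.3, n))
        r = 10.0
        Y = rng.negative_binomial(r, r / (r + mu[:, None] * lib[None, :]))
        cols = [f"d{i}" for i in range(n)]
        return scpipe.Pseudobulk(
            counts=pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)],
                                columns=cols),
            groups=pd.Series(["case"] * 6 + ["control"] * 6, index=cols),
        )

    def test_donor_permutation_within_group_invariance(self):
        pb = self._null_pb(0)
        de1 = scpipe.nb_ql_test(pb)
        perm_cols = ["d2", "d0", "d1", "d5", "d3", "d4",
                     "d8", "d6", "d7", "d11", "d9", "d10"]
        pb2 = scpipe.Pseudobulk(counts=pb.counts[perm_cols],
                                groups=pb.groups[perm_cols])
        de2 = scpipe.nb_ql_test(pb2)
        assert np.allclose(de1["F"], de2["F"])
        assert np.allclose(de1["p"], de2["p"])

    def test_planted_twofold_genes_detected(self):
        rng = np.random.default_rng(1)
        n_genes, n = 1000, 12
        mu = np.full(n_genes, 100.0)
        lib = np.exp(rng.normal(0, 0.3, n))
        de_idx = rng.choice(n_genes, 100, replace=False)
        M = mu[:, None] * lib[None, :]
        M[np.ix_(de_idx, np.arange(6))] *= 2.0
        r = 10.0
        Y = rng.negative_binomial(r, r / (r + M))
        cols = [f"d{i}" for i in range(n)]
        pb = scpipe.Pseudobulk(
            counts=pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)],
                                columns=cols),
            groups=pd.Series(["case"] * 6 + ["control"] * 6, index=cols),
        )
        de = scpipe.nb_ql_test(pb)
        called = set(de.index[de["q"] < 0.1])
        sens = len(called & {f"g{i}" for i in de_idx}) / 100
        assert sens >= 0.7
        # planted direction: log2FC positive for up genes
        assert de.loc[[f"g{i}" for i in de_idx], "log2FC"].median() == pytest.approx(
            1.0, abs=0.25
        )

    def test_single_donor_group_rejected(self):
        pb = self._null_pb(0)
        cols = ["d0", "d6", "d7", "d8"]
        pb2 = scpipe.Pseudobulk(counts=pb.counts[cols], groups=pb.groups[cols])
        with pytest.raises(ValueError, match="donors"):
            scpipe.nb_ql_test(pb2)
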