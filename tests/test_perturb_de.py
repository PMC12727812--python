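import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse
from scipy import stats as sps

from tilescreen import synthetic_data as syn
from tilescreen.perturb_de import (
    PseudobulkCounts,
    calibrate_cis,
    de_all_sgrnas,
    de_test,
    filter_genes_by_detection,
    pair_distances,
    pseudobulk,
    trans_profile,
)
from tilescreen.sc_assign import AssignmentTable
from tilescreen.screen_stats import benjamini_hochberg


def assignment_of(pairs, mode="low"):
    tab = pd.DataFrame(pairs, columns=["cell", "sgrna"])
    tab["posterior"] = 1.0
    per_cell = tab.groupby("cell").size()
    cells = per_cell[per_cell == 1].index if mode == "low" else per_cell.index
    return AssignmentTable(tab, mode, pd.Index(cells))


def small_adata(X, wells, gene_ids=None):
    X = np.asarray(X)
    obs = pd.DataFrame(
        {"gem_well": wells}, index=[f"c{i}" for i in range(X.shape[0])]
    )
    var = pd.DataFrame(index=gene_ids or [f"gene{j}" for j in range(X.shape[1])])
    return ad.AnnData(X=sparse.csr_matrix(X.astype(float)), obs=obs, var=var)


class TestPseudobulk:
    def test_exact_sums_per_well(self):
        X = [[1, 2], [3, 4], [10, 10], [100, 100]]
        adata = small_adata(X, ["w0", "w0", "w0", "w0"])
        assign = assignment_of([("c0", "sgA"), ("c1", "sgA"),
                                ("c2", "nt0"), ("c3", "nt0")])
        info = pd.DataFrame({"category": ["hdel", "non-targeting"],
                             "hdel_id": ["h1", ""]}, index=["sgA", "nt0"])
        pb = pseudobulk(adata, assign, "sgA", "nontargeting", info)
        assert pb.counts[("target", "w0")].tolist() == [4, 6]
        assert pb.counts[("reference", "w0")].tolist() == [110, 110]

    def test_total_umis_conserved(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(5, size=(40, 6))
        wells = [f"w{i % 3}" for i in range(40)]
        adata = small_adata(X, wells)
        pairs = [(f"c{i}", "sgA" if i < 15 else "nt0") for i in range(40)]
        assign = assignment_of(pairs)
        info = pd.DataFrame({"category": ["hdel", "non-targeting"],
                             "hdel_id": ["h1", ""]}, index=["sgA", "nt0"])
        pb = pseudobulk(adata, assign, "sgA", "nontargeting", info)
        assert pb.counts.sum(axis=1).tolist() == X.sum(axis=0).tolist()

    def test_same_hdel_cells_excluded_from_v4_reference(self):
        X = np.ones((3, 2))
        adata = small_adata(X, ["w0", "w0", "w0"])
        assign = assignment_of(
            [("c0", "sgA"), ("c1", "sgB"), ("c2", "sgC")], mode="high"
        )
        info = pd.DataFrame({
            "category": ["hdel", "hdel", "hdel"],
            "hdel_id": ["h1", "h1", "h2"],  # sgB targets the same hDel as sgA
        }, index=["sgA", "sgB", "sgC"])
        pb = pseudobulk(adata, assign, "sgA", "other", info)
        # reference = all other cells minus same-hDel carriers = only c2
        assert pb.n_reference_cells == 1
        assert pb.counts[("reference", "w0")].tolist() == [1, 1]

    def test_unassigned_sgrna_errors(self):
        adata = small_adata(np.ones((2, 2)), ["w0", "w0"])
        assign = assignment_of([("c0", "nt0")])
        info = pd.DataFrame({"category": ["non-targeting"], "hdel_id": [""]},
                            index=["nt0"])
        with pytest.raises(ValueError):
            pseudobulk(adata, assign, "sgZZ", "nontargeting", info)


class TestDeTest:
    def _pb(self, target, reference, wells=("w0", "w1")):
        cols = {}
        for w, t, r in zip(wells, target, reference):
            cols[("target", w)] = pd.Series(t)
            cols[("reference", w)] = pd.Series(r)
        counts = pd.DataFrame(cols)
        counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["group", "well"])
        counts.index = [f"gene{j}" for j in range(counts.shape[0])]
        return PseudobulkCounts(counts, "sgA", 10, 10)

    def test_identical_groups_are_null(self):
        base = [[200, 300, 400]] * 2
        pb = self._pb(base, base)
        res = de_test(pb)
        assert (res["p_lrt"] > 0.9).all()
        assert res["log2fc"].abs().max() < 1e-6

    def test_single_well_rejected(self):
        pb = self._pb([[10, 20]], [[10, 20]], wells=("w0",))
        with pytest.raises(ValueError):
            de_test(pb)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(5)
        n_genes = 300
        mu = rng.lognormal(5, 1, n_genes)
        cols = {}
        for g in ("target", "reference"):
            for w in ("w0", "w1", "w2"):
                cols[(g, w)] = rng.poisson(mu)
        counts = pd.DataFrame(cols, index=[f"g{j}" for j in range(n_genes)])
        counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["group", "well"])
        res = de_test(PseudobulkCounts(counts, "sgA", 10, 10))
        assert sps.kstest(res["p_lrt"].dropna(), "uniform").pvalue > 0.01

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(6)
        n_genes = 60
        mu = rng.lognormal(6, 0.5, n_genes)
        effect = np.ones(n_genes)
        effect[0] = 2 ** -0.4
        cols = {}
        for w in ("w0", "w1", "w2", "w3", "w4"):
            cols[("target", w)] = rng.poisson(mu * effect)
            cols[("reference", w)] = rng.poisson(mu)
        counts = pd.DataFrame(cols, index=[f"g{j}" for j in range(n_genes)])
        counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["group", "well"])
        res = de_test(PseudobulkCounts(counts, "sgA", 150, 150))
        assert res["log2fc"].iloc[0] == pytest.approx(-0.4, abs=0.1)
        assert res["p_lrt"].iloc[0] < 1e-3

    def test_gene_detection_filter_runs_on_cells(self):
        X = np.zeros((100, 3))
        X[:, 0] = 1  # detected everywhere
        X[:5, 1] = 1  # detected in 5% of cells
        X[:20, 2] = 1  # detected in 20%
        adata = small_adata(X, ["w0"] * 100)
        kept = filter_genes_by_detection(adata, min_cell_fraction=0.10)
        assert list(kept.var_names) == ["gene0", "gene2"]


class TestCisCalibration:
    def _frame(self, null_t, cis_t, gene="geneA"):
        # one focal gene; null sgRNAs target a distant chromosome
        rows = []
        for i, t in enumerate(null_t):
            rows.append((f"far{i}", gene, t, 1.0))
        rows.append(("near0", gene, cis_t, 1.0))
        de = pd.DataFrame(rows, columns=["sgrna", "gene", "log2fc", "se"])
        info = pd.DataFrame({
            "chrom": ["chr9"] * len(null_t) + ["chr1"],
            "target_mid": [0] * len(null_t) + [1000],
            "hdel_id": "h",
            "category": "hdel",
        }, index=de["sgrna"])
        genes = pd.DataFrame({"gene_id": [gene], "chrom": ["chr1"], "tss": [2000]})
        return de, info, genes

    def test_z_is_standardized_against_gene_null(self):
        rng = np.random.default_rng(8)
        null_t = rng.normal(size=60)
        null_t = (null_t - null_t.mean()) / null_t.std(ddof=1)  # exact mean 0, sd 1
        de, info, genes = self._frame(null_t, cis_t=1.96)
        res = calibrate_cis(de, info, genes)
        row = res[res["sgrna"] == "near0"].iloc[0]
        assert row["z"] == pytest.approx(1.96, abs=1e-9)
        assert row["p"] == pytest.approx(2 * sps.norm.sf(1.96), abs=1e-9)
        assert row["q"] == row["q"]  # in-universe pair gets a q

    def test_t_at_null_mean_gives_p_one(self):
        null_t = np.concatenate([np.linspace(-2, 2, 50)])
        de, info, genes = self._frame(null_t, cis_t=0.0)
        res = calibrate_cis(de, info, genes)
        row = res[res["sgrna"] == "near0"].iloc[0]
        assert row["z"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_distal_pairs_carry_no_q(self):
        de, info, genes = self._frame(np.linspace(-2, 2, 60), cis_t=3.0)
        info.loc["near0", "target_mid"] = 200_000  # 198 kb from TSS
        res = calibrate_cis(de, info, genes)
        assert res.loc[res["sgrna"] == "near0", "q"].isna().all()
        assert res.loc[res["sgrna"] != "near0", "q"].isna().all()  # cross-chrom

    def test_location_scale_invariance(self):
        rng = np.random.default_rng(9)
        null_t = rng.normal(size=80)
        de, info, genes = self._frame(null_t, cis_t=2.5)
        z1 = calibrate_cis(de, info, genes).set_index("sgrna")["z"]
        de2 = de.copy()
        de2["log2fc"] = de2["log2fc"] + 5.0  # shift every t of the gene
        z2 = calibrate_cis(de2, info, genes).set_index("sgrna")["z"]
        assert np.allclose(z1.dropna(), z2.dropna())

    def test_few_null_pairs_flags_gene(self):
        de, info, genes = self._frame(np.linspace(-1, 1, 10), cis_t=2.0)
        res = calibrate_cis(de, info, genes, min_null_pairs=50)
        assert res["flagged_gene"].all()
        assert res["p"].isna().all()

    def test_pair_distance_uses_midpoint_to_tss(self):
        de = pd.DataFrame([("sgA", "geneA", 0.0, 1.0)],
                          columns=["sgrna", "gene", "log2fc", "se"])
        info = pd.DataFrame({"chrom": ["chr1"], "target_mid": [500]}, index=["sgA"])
        genes = pd.DataFrame({"gene_id": ["geneA"], "chrom": ["chr1"], "tss": [1700]})
        assert pair_distances(de, info, genes).iloc[0] == 1200


class TestTransProfile:
    def _planted_program(self, seed=60):
        fx = syn.generate_genome_fixture(seed=1)
        rng = np.random.default_rng(seed)
        h = fx.hdels.iloc[0]
        rows = [(f"sg{i}", "G" + "".join(rng.choice(list("ACGT"), 19)), "hdel",
                 h.chrom, h.start, h.start + 20, h["name"]) for i in range(2)]
        rows += [(f"nt{i}", "G" + "".join(rng.choice(list("ACGT"), 19)),
                  "non-targeting", None, None, None, "") for i in range(3)]
        man = pd.DataFrame(
            rows, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
        )
        program_genes = [g for g in fx.genes["gene_id"][:10]]
        trans = [(sg, g, 0.5 * (-1) ** k)
                 for sg in ("sg0", "sg1")
                 for k, g in enumerate(program_genes)]
        truth = syn.make_perturb_truth(
            man, fx, moi_mode="low", target_moi=2.0, trans_effects=trans, seed=seed
        )
        data = syn.simulate_perturbseq(truth, n_cells=4000, seed=seed + 1)
        return fx, man, data, program_genes, h["name"]

    def test_program_recovery_and_sgrna_correlation(self):
        fx, man, data, program_genes, hdel_id = self._planted_program()
        from tilescreen.sc_assign import assign_sgrnas, fit_all_sgrnas

        fits = fit_all_sgrnas(data.sgrnas, seed=61)
        table = assign_sgrnas(data.sgrnas, fits, mode="low")
        info = man.set_index("id")
        per = de_all_sgrnas(data.genes, table, info, policy="nontargeting")
        res = trans_profile(
            data.genes, table, info, hdel_id,
            policy="nontargeting", fdr=0.1, per_sgrna_stats=per,
        )
        hits = set(res["hits"].index)
        assert len(hits & set(program_genes)) >= 8
        false = hits - set(program_genes)
        assert len(false) <= 2
        signs = res["hits"].loc[sorted(hits & set(program_genes)), "direction"]
        assert set(signs) <= {"up", "down"}
        if res["correlation"] is not None:
            off_diag = res["correlation"].iloc[0, 1]
            assert off_diag > 0.5

    def test_null_has_no_hits(self):
        fx = syn.generate_genome_fixture(seed=1)
        rng = np.random.default_rng(70)
        h = fx.hdels.iloc[0]
        rows = [("sg0", "G" + "".join(rng.choice(list("ACGT"), 19)), "hdel",
                 h.chrom, h.start, h.start + 20, h["name"])]
        rows += [(f"nt{i}", "G" + "".join(rng.choice(list("ACGT"), 19)),
                  "non-targeting", None, None, None, "") for i in range(3)]
        man = pd.DataFrame(
            rows, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
        )
        truth = syn.make_perturb_truth(man, fx, moi_mode="low", target_moi=2.0, seed=71)
        data = syn.simulate_perturbseq(truth, n_cells=3000, seed=72)
        from tilescreen.sc_assign import assign_sgrnas, fit_all_sgrnas

        fits = fit_all_sgrnas(data.sgrnas, seed=73)
        table = assign_sgrnas(data.sgrnas, fits, mode="low")
        res = trans_profile(data.genes, table, man.set_index("id"), h["name"],
                            policy="nontargeting", fdr=0.1)
        assert len(res["hits"]) <= 2
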