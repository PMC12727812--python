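import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tilescreen import screen_stats as ss
from tilescreen import synthetic_data as syn
from conftest import tiling_screen


def make_counts(mat, timepoints=None, replicates=None, individuals=None):
    mat = pd.DataFrame(np.asarray(mat))
    mat.index = [f"sg{i}" for i in range(mat.shape[0])]
    n = mat.shape[1]
    timepoints = timepoints or (["t0", "tfinal"] * n)[:n]
    samples = pd.DataFrame({
        "sample": [f"s{j}" for j in range(n)],
        "timepoint": timepoints,
        "replicate": replicates or [f"rep{j // 2}" for j in range(n)],
        "individual": individuals or ["ind0"] * n,
    })
    mat.columns = samples["sample"]
    return ss.ScreenCounts(counts=mat, samples=samples)


class TestSizeFactors:
    def test_two_sample_median_of_ratios(self):
        sc = make_counts([[10, 20], [100, 200]])
        sf = ss.size_factors(sc)
        assert sf.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns_give_unit_factors(self):
        sc = make_counts([[5, 5], [70, 70], [3, 3]])
        assert ss.size_factors(sc).to_numpy() == pytest.approx([1.0, 1.0])

    def test_single_control_feature(self):
        sc = make_counts([[7, 14], [100, 1]])
        sf = ss.size_factors(sc, control_ids=["sg0"])
        assert sf.to_numpy() == pytest.approx([1 / np.sqrt(2), np.sqrt(2)])

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(100, size=(50, 4)) + 1
        a = ss.size_factors(make_counts(mat))
        b = ss.size_factors(make_counts(mat * 7))
        assert a.to_numpy() == pytest.approx(b.to_numpy())

    def test_all_zero_feature_matrix_errors(self):
        with pytest.raises(ValueError):
            ss.size_factors(make_counts([[0, 1], [1, 0]]))


class TestNbGlm:
    def test_identical_timepoints_are_null(self):
        mat = np.tile([[50], [500], [2000]], (1, 4))
        res = ss.fit_nb_glm(make_counts(mat), design=("time",))
        assert res["log2fc"].abs().max() < 1e-6
        assert (res["p"] > 0.99).all()

    def test_poisson_limit_matches_closed_form(self):
        # alpha = 0, one sample per timepoint: MLE is the normalized ratio
        mat = np.array([[100, 220], [400, 300]])
        sc = make_counts(mat)
        sf = pd.Series([1.0, 1.1], index=sc.counts.columns)
        disp = pd.Series(0.0, index=sc.counts.index)
        res = ss.fit_nb_glm(sc, design=("time",), sf=sf, dispersion=disp)
        expected = np.log2((mat[:, 1] / 1.1) / (mat[:, 0] / 1.0))
        assert res["log2fc"].to_numpy() == pytest.approx(expected, abs=1e-5)

    def test_planted_lfc_recovered_and_tails_consistent(self):
        n = 400
        ids = [f"sg{i}" for i in range(2 * n)]
        man = pd.DataFrame({
            "id": ids, "spacer": "G" * 20,
            "category": ["hdel"] * n + ["non-targeting"] * n,
            "chrom": "chr1", "start": 0, "end": 20,
        })
        truth = syn.make_screen_truth(man, depth=1000, dispersion=0.1, seed=1)
        truth.lfc[:n] = 1.0
        sc = syn.simulate_screen(man, truth, seed=2)
        res = ss.fit_nb_glm(sc, design=("time",), control_ids=ids[n:])
        assert res["log2fc"].iloc[:n].mean() == pytest.approx(1.0, abs=0.05)
        # tail p-values complement each other
        assert np.allclose(
            res["p_depleted"] + res["p_enriched"], 1.0, atol=1e-12
        )
        z = res["wald_z"]
        assert ((res["p"] < 0.05) == (z.abs() > sps.norm.ppf(0.975))).all()

    def test_all_zero_row_excluded_not_fatal(self):
        mat = np.array([[0, 0, 0, 0], [100, 110, 90, 105]])
        res = ss.fit_nb_glm(make_counts(mat), design=("time",))
        assert bool(res["excluded"].iloc[0]) and res["reason"].iloc[0] == "all_zero"
        assert not res["excluded"].iloc[1]

    def test_rank_deficient_design_errors(self):
        sc = make_counts(
            np.ones((3, 4)) * 50,
            timepoints=["t0", "t0", "tfinal", "tfinal"],
            individuals=["i0", "i0", "i1", "i1"],  # individual == time
        )
        with pytest.raises(ValueError):
            ss.fit_nb_glm(sc, design=("individual", "time"))


class TestExclusions:
    def _stats(self, ids, lfc=0.0, pct=50.0):
        return pd.DataFrame(
            {"log2fc": lfc, "t0_percentile": pct},
            index=pd.Index(ids, name="id"),
        )

    @pytest.mark.parametrize(
        "spacer, excluded, reason",
        [
            ("ACTGACTG" + "GGGG" + "ACTGACTG", True, "G4_after_position_5"),  # G4 at 9
            ("ACTGACTGAC" + "CCCC" + "ACTGAC", True, "C4_position_10_12"),  # C4 at 11
            ("AGGGGTACGTACGTACGTAC", False, ""),  # G4 at 2: retained
            ("ACTG" + "GGGGG" + "ACGTACGTACG", True, "G4_after_position_5"),  # run 5-9 has G4 at 6
            ("ACTGACTGCCCCACTGACTG", False, ""),  # C4 at 9: outside 10-12
        ],
    )
    def test_homopolymer_rules(self, spacer, excluded, reason):
        man = pd.DataFrame({"id": ["sg0"], "spacer": [spacer]})
        out = ss.apply_screen_exclusions(man, self._stats(["sg0"]))
        assert bool(out["excluded"].iloc[0]) is excluded
        assert out["reason"].iloc[0] == reason

    def test_enriched_low_abundance_boundary(self):
        man = pd.DataFrame({
            "id": ["a", "b", "c", "d"],
            "spacer": ["GACTGACTGACTGACTGACT"] * 4,
        })
        stats = self._stats(["a", "b", "c", "d"])
        stats["log2fc"] = [1.5, 1.5, 0.9, 1.5]
        stats["t0_percentile"] = [3.0, 5.0, 3.0, 5.1]
        out = ss.apply_screen_exclusions(man, stats)
        assert out["excluded"].tolist() == [True, True, False, False]
        assert out.loc["a", "reason"] == "enriched_low_abundance"


class TestWindows:
    def test_single_window_covers_whole_hdel(self):
        man, hdels, _, _ = tiling_screen(n_hdels=1, guides_per_hdel=6)
        wmap = ss.assign_windows(man, hdels, ss.WindowScheme(250, 250, 5))
        assert wmap["window_id"].nunique() == 1
        assert (wmap["start"] == 0).all() and (wmap["end"] == 250).all()

    def test_overlapping_windows_share_guides(self):
        hdels = pd.DataFrame(
            [("chr1", 0, 1000, "h1")], columns=["chrom", "start", "end", "name"]
        )
        man = pd.DataFrame({
            "id": [f"g{i}" for i in range(20)], "spacer": "G" * 20,
            "category": "hdel", "chrom": "chr1",
            "start": np.full(20, 250), "end": np.full(20, 270), "hdel_id": "h1",
        })
        wmap = ss.assign_windows(man, hdels, ss.WindowScheme(500, 250, 5))
        by_guide = wmap[wmap["sgrna"] == "g0"]
        # midpoint 260 belongs to [0, 500) and [250, 750)
        assert sorted(zip(by_guide["start"], by_guide["end"])) == [(0, 500), (250, 750)]

    def test_windows_below_min_guides_dropped(self):
        man, hdels, _, _ = tiling_screen(n_hdels=1, guides_per_hdel=4)
        wmap = ss.assign_windows(man, hdels, ss.WindowScheme(250, 250, 5))
        assert wmap.empty


class TestAlphaRra:
    def test_beta_closed_forms(self):
        assert ss._rho_from_sorted(np.array([0.2]), alpha=0.5)[0] == pytest.approx(0.2)
        rho = ss._rho_from_sorted(np.array([0.01, 0.5, 0.9]), alpha=0.05)[0]
        assert rho == pytest.approx(1 - (1 - 0.01) ** 3)
        assert ss._rho_from_sorted(np.array([0.3, 0.4]), alpha=0.1)[0] == 1.0

    def test_permutation_p_matches_exhaustive_enumeration(self):
        # pool of N = 4 guides; window of n = 2: the implementation's null must
        # equal brute-force enumeration over all 16 ordered draws
        ids = ["g0", "g1", "g2", "g3"]
        stats = pd.DataFrame({
            "p_depleted": [1e-6, 1e-5, 0.6, 0.9],
            "p_enriched": [1 - 1e-6, 1 - 1e-5, 0.4, 0.1],
            "log2fc": [-2.0, -1.5, 0.0, 0.2],
            "wald_z": [-5.0, -4.0, 0.2, 1.0],
            "excluded": False,
        }, index=ids)
        wmap = pd.DataFrame({
            "window_id": "w0", "hdel_id": "h0", "chrom": "chr1",
            "start": 0, "end": 250, "sgrna": ["g0", "g1"],
        })
        res = ss.alpha_rra(wmap, stats, ss.RraConfig(seed=0, n_permutations=1000))
        # brute-force oracle: BH over depletion tail gives alpha = 2/4;
        # observed percentiles {0.25, 0.5}
        grid = np.array([0.25, 0.5, 0.75, 1.0])
        alpha = 0.5
        obs = ss._rho_from_sorted(np.sort(np.array([0.25, 0.5])), alpha)[0]
        rhos = [
            ss._rho_from_sorted(np.sort(np.array(draw)), alpha)[0]
            for draw in itertools.product(grid, repeat=2)
        ]
        exact_p = (1 + sum(r <= obs for r in rhos)) / (1 + 16)
        assert exact_p == pytest.approx(5 / 17)  # hand enumeration
        assert res.loc["w0", "rho"] == pytest.approx(obs)
        assert res.loc["w0", "p"] == pytest.approx(exact_p)
        assert res.loc["w0", "direction"] == "depleted"

    def test_recovers_planted_window(self):
        man, hdels, counts, planted = tiling_screen(
            n_hdels=40, planted=[0, 7], lfc=-2.0, depth=800, seed=5
        )
        stats = ss.fit_nb_glm(counts, design=("time",))
        wmap = ss.assign_windows(man, hdels, ss.WindowScheme(250, 250, 5))
        res = ss.alpha_rra(wmap, stats, ss.RraConfig(seed=6))
        hits = res[res["q"] < 0.1]
        assert set(hits["hdel_id"]) == set(planted)
        assert (hits["direction"] == "depleted").all()
        assert res["rho"].between(0, 1).all()
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_no_significant_guides_flags_degenerate_alpha(self):
        man, hdels, counts, _ = tiling_screen(n_hdels=10, seed=8)
        stats = ss.fit_nb_glm(counts, design=("time",))
        stats["p_depleted"] = stats["p_enriched"] = 0.5  # force no signal
        res = ss.alpha_rra(wmap := ss.assign_windows(man, hdels, ss.WindowScheme(250, 250, 5)),
                           stats, ss.RraConfig(seed=9))
        assert res["degenerate_alpha"].all()
        assert (res["rho"] == 1.0).all()


class TestStouffer:
    def _map_and_stats(self, zs):
        stats = pd.DataFrame({
            "wald_z": zs, "log2fc": 0.0, "excluded": False,
        }, index=[f"g{i}" for i in range(len(zs))])
        wmap = pd.DataFrame({
            "window_id": "w0", "hdel_id": "h0", "chrom": "chr1",
            "start": 0, "end": 250, "sgrna": stats.index,
        })
        return wmap, stats

    @pytest.mark.parametrize(
        "zs, expected",
        [([1.0, 1.0], np.sqrt(2)), ([0.0, 0.0, 0.0], 0.0), ([2.0, -2.0], 0.0)],
    )
    def test_combined_z_closed_forms(self, zs, expected):
        wmap, stats = self._map_and_stats(zs)
        res = ss.stouffer_windows(wmap, stats, standardize=False, null="normal")
        assert res["stouffer_z"].iloc[0] == pytest.approx(expected)
        if expected == 0.0:
            assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_equals_naive_oracle_on_simulated_screen(self):
        man, hdels, counts, _ = tiling_screen(n_hdels=30, seed=11)
        stats = ss.fit_nb_glm(counts, design=("time",))
        wmap = ss.assign_windows(man, hdels, ss.WindowScheme(250, 250, 5))
        res = ss.stouffer_windows(wmap, stats, standardize=False, null="normal")
        for wid, sub in wmap.groupby("window_id"):
            z = stats.loc[sub["sgrna"], "wald_z"].to_numpy()
            assert res.loc[wid, "stouffer_z"] == pytest.approx(
                z.sum() / np.sqrt(len(z))
            )


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        q = ss.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert ss.benjamini_hochberg([0.37])[0] == pytest.approx(0.37)
        assert ss.benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = ss.benjamini_hochberg(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestHomopolymerEnrichment:
    def test_fold_arithmetic(self):
        # 10/10 significant in the G-at-1 group, 20/110 overall
        ids = [f"g{i}" for i in range(110)]
        spacers = ["GGGG" + "A" * 16] * 10 + ["GACTGACTGACTGACTGACT"] * 100
        man = pd.DataFrame({"id": ids, "spacer": spacers})
        q = np.array([0.01] * 10 + [0.01] * 10 + [0.5] * 90)
        stats = pd.DataFrame({"q": q, "excluded": False}, index=ids)
        out = ss.homopolymer_enrichment(man, stats)
        row = out[(out["base"] == "G") & (out["position"] == 1)].iloc[0]
        assert row["frac_significant"] == pytest.approx(1.0)
        assert row["fold"] == pytest.approx(1.0 / (20 / 110))
        assert not row["small_group"]

    def test_small_groups_flagged(self):
        man = pd.DataFrame({"id": ["a"], "spacer": ["GAAAA" + "C" * 15]})
        stats = pd.DataFrame({"q": [0.5], "excluded": [False]}, index=["a"])
        out = ss.homopolymer_enrichment(man, stats)
        assert out["small_group"].all()
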