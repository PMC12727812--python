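"""Self-calibration experiments exercising every pipeline stage end to end.

Each function builds its own synthetic inputs with planted ground truth,
runs the corresponding pipeline stage, and returns the measured quantities
(recovery rates, calibration statistics, arithmetic checks). They are used
by the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import guide_library as gl
from . import screen_stats as ss
from . import synthetic_data as syn
from .intervals import GenomicInterval, as_interval_frame, intersection_bp, total_bp


# ---------------------------------------------------------------------------
# library manifest arithmetic
# ---------------------------------------------------------------------------

def _component(n: int, prefix: str, offset: int) -> pd.DataFrame:
    def spacer(i):
        code = np.base_repr(i, base=4).zfill(19)
        return "G" + "".join("ACGT"[int(c)] for c in code)

    return pd.DataFrame({
        "id": [f"{prefix}_{i}" for i in range(n)],
        "spacer": [spacer(i + offset) for i in range(n)],
    })


def manifest_totals() -> dict:
    """Assemble screen manifests from the published component sizes.

    The deep tiling library combines 78,270 hDel-targeting, 2,000
    non-targeting, 600 essential-promoter and 394 proliferation-suppressor
    sgRNAs; the low-MOI single-cell library 122 + 18 + 10 + 10; the high-MOI
    single-cell library 888 + 25 + 10.
    """
    totals = {}
    specs = {
        "v2": [("hdel", 78_270), ("non-targeting", 2_000),
               ("essential", 600), ("proliferation-suppressor", 394)],
        "v3": [("hdel", 122), ("TSS", 18), ("non-targeting", 10),
               ("putative-CRE", 10)],
        "v4": [("hdel", 888), ("non-targeting", 25), ("putative-CRE", 10)],
    }
    for version, comps in specs.items():
        off = 0
        parts = {}
        for name, n in comps:
            parts[name] = _component(n, f"{version}_{name}", off)
            off += n
        totals[version] = len(gl.assemble_manifest(parts))
    return totals


# ---------------------------------------------------------------------------
# alpha-RRA closed forms and exhaustive enumeration
# ---------------------------------------------------------------------------

def rra_closed_forms() -> dict:
    """Beta order-statistic closed forms and the exhaustive permutation check."""
    out = {
        "rho_n1": float(ss._rho_from_sorted(np.array([0.2]), alpha=0.5)[0]),
        "rho_k1_n3": float(
            ss._rho_from_sorted(np.array([0.01, 0.5, 0.9]), alpha=0.05)[0]
        ),
    }
    # pool N = 4, window n = 2: implementation versus brute-force enumeration
    stats = pd.DataFrame({
        "p_depleted": [1e-6, 1e-5, 0.6, 0.9],
        "p_enriched": [1 - 1e-6, 1 - 1e-5, 0.4, 0.1],
        "log2fc": [-2.0, -1.5, 0.0, 0.2],
        "wald_z": [-5.0, -4.0, 0.2, 1.0],
        "excluded": False,
    }, index=["g0", "g1", "g2", "g3"])
    wmap = pd.DataFrame({
        "window_id": "w0", "hdel_id": "h0", "chrom": "chr1",
        "start": 0, "end": 250, "sgrna": ["g0", "g1"],
    })
    res = ss.alpha_rra(wmap, stats, ss.RraConfig(seed=0, n_permutations=1000))
    grid = np.array([0.25, 0.5, 0.75, 1.0])
    obs = ss._rho_from_sorted(np.sort(np.array([0.25, 0.5])), 0.5)[0]
    rhos = [
        ss._rho_from_sorted(np.sort(np.array(d)), 0.5)[0]
        for d in itertools.product(grid, repeat=2)
    ]
    out["perm_p_impl"] = float(res.loc["w0", "p"])
    out["perm_p_exhaustive"] = (1 + sum(r <= obs for r in rhos)) / 17
    return out


# ---------------------------------------------------------------------------
# global-null screen: Stouffer calibration
# ---------------------------------------------------------------------------

def _null_screen(n_guides: int, seed: int, n_replicates: int = 3):
    man = pd.DataFrame({
        "id": [f"sg{i}" for i in range(n_guides)], "spacer": "G" * 20,
        "category": "hdel", "chrom": "chr1",
        "start": np.arange(n_guides) * 30, "end": np.arange(n_guides) * 30 + 20,
        "hdel_id": [f"h{i // 5:04d}" for i in range(n_guides)],
    })
    truth = syn.make_screen_truth(
        man, depth=500, dispersion=0.05, n_replicates=n_replicates, seed=seed
    )
    counts = syn.simulate_screen(man, truth, seed=seed + 1)
    return man, counts


def stouffer_null_calibration(seed: int = 21, n_windows: int = 2000) -> dict:
    """Stouffer Z versus the naive oracle and its null distribution.

    Simulates a no-effect screen of ``n_windows`` x 5 sgRNAs, fits the NB
    engine, aggregates 5-guide windows, and returns the max |Z - oracle|
    discrepancy plus the KS test of the window Z against N(0,1).
    """
    man, counts = _null_screen(n_windows * 5, seed)
    stats = ss.fit_nb_glm(counts, design=("time",))
    # windows defined directly from the manifest blocks of 5
    wmap = pd.DataFrame({
        "window_id": man["hdel_id"], "hdel_id": man["hdel_id"],
        "chrom": "chr1", "start": 0, "end": 150, "sgrna": man["id"],
    })
    res = ss.stouffer_windows(wmap, stats)
    # independent oracle: standardize z the same way, sum/sqrt(n) by hand
    z = stats.loc[~stats["excluded"], "wald_z"]
    zs = (z - z.median()) / (1.4826 * (z - z.median()).abs().median())
    oracle = zs.groupby(man.set_index("id")["hdel_id"]).apply(
        lambda v: v.sum() / np.sqrt(len(v))
    )
    diff = float((res["stouffer_z"] - oracle.loc[res.index]).abs().max())
    ks = sps.kstest(res["stouffer_z"].to_numpy(), "norm")
    return {
        "max_oracle_diff": diff,
        "window_z_sd": float(res["stouffer_z"].std()),
        "ks_p": float(ks.pvalue),
        "n_windows": len(res),
    }


# ---------------------------------------------------------------------------
# NB engine recovery
# ---------------------------------------------------------------------------

def nb_lfc_recovery(seed: int = 11, n_sgrnas: int = 2000) -> dict:
    """Mean recovered log2FC for sgRNAs planted at +1 against null controls,
    with control-based normalization, plus the Poisson closed-form check."""
    ids = [f"sg{i}" for i in range(n_sgrnas)] + [f"nt{i}" for i in range(n_sgrnas)]
    man = pd.DataFrame({
        "id": ids, "spacer": "G" * 20,
        "category": ["hdel"] * n_sgrnas + ["non-targeting"] * n_sgrnas,
        "chrom": "chr1", "start": 0, "end": 20,
    })
    truth = syn.make_screen_truth(man, depth=1000, dispersion=0.1, seed=seed)
    truth.lfc[:n_sgrnas] = 1.0
    counts = syn.simulate_screen(man, truth, seed=seed + 1)
    res = ss.fit_nb_glm(
        counts, design=("time",), control_ids=[f"nt{i}" for i in range(n_sgrnas)]
    )
    mean_lfc = float(res["log2fc"].iloc[:n_sgrnas].mean())

    # Poisson limit: alpha = 0, one sample per timepoint -> closed form
    mat = np.array([[100, 220], [400, 300], [50, 75]])
    pc = pd.DataFrame(mat, index=["a", "b", "c"], columns=["s0", "s1"])
    samples = pd.DataFrame({
        "sample": ["s0", "s1"], "timepoint": ["t0", "tfinal"],
        "replicate": ["rep0", "rep0"], "individual": ["ind0", "ind0"],
    })
    sc = ss.ScreenCounts(pc, samples)
    sf = pd.Series([1.0, 1.25], index=["s0", "s1"])
    disp = pd.Series(0.0, index=pc.index)
    pois = ss.fit_nb_glm(sc, design=("time",), sf=sf, dispersion=disp)
    closed = np.log2((mat[:, 1] / 1.25) / (mat[:, 0] / 1.0))
    return {
        "mean_planted_lfc": mean_lfc,
        "poisson_max_abs_err": float(np.abs(pois["log2fc"].to_numpy() - closed).max()),
    }


# ---------------------------------------------------------------------------
# mixture EM recovery
# ---------------------------------------------------------------------------

def mixture_recovery(seed: int = 7, n_cells: int = 5000) -> dict:
    """Generator-fitter conjugacy: parameter recovery and assignment quality
    at signal/background separation >= 4."""
    from .distributions import sample_log2_gaussian
    from .sc_assign import fit_sgrna_mixture, posterior_signal

    rng = np.random.default_rng(seed)
    lam, mu, sigma, pi = 0.3, 8.0, 1.0, 0.2
    infected = rng.random(n_cells) < pi
    c = rng.poisson(lam, n_cells)
    c[infected] = sample_log2_gaussian(rng, mu, sigma, int(infected.sum()))
    fit = fit_sgrna_mixture(c, seed=seed + 1)
    tr = np.array(fit.loglik_trace)
    monotone = bool(
        (np.diff(tr) >= -1e-8 * np.maximum(np.abs(tr[:-1]), 1.0)).all()
    )
    post = posterior_signal(fit, c)
    assigned = post > 0.5
    tp = int((assigned & infected).sum())
    precision = tp / max(int(assigned.sum()), 1)
    recall = tp / max(int(infected.sum()), 1)
    return {
        "separation": mu - np.log2(lam + 1),
        "abs_err_lambda": abs(fit.lam - lam),
        "abs_err_mu": abs(fit.mu - mu),
        "abs_err_pi": abs(fit.pi - pi),
        "loglik_monotone": monotone,
        "converged": bool(fit.converged),
        "precision": precision,
        "recall": recall,
    }


def moi_recovery(seed: int = 20, n_cells: int = 5000, n_sgrnas: int = 50) -> dict:
    """High-MOI regime: realized and re-assigned median sgRNAs per cell."""
    from .sc_assign import assign_sgrnas, fit_all_sgrnas

    fx = syn.generate_genome_fixture(seed=1)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sgrnas):
        h = fx.hdels.iloc[i % len(fx.hdels)]
        rows.append((f"sg{i}", "G" + "".join(rng.choice(list("ACGT"), 19)),
                     "hdel", h.chrom, h.start, h.start + 20, h["name"]))
    man = pd.DataFrame(
        rows, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
    )
    truth = syn.make_perturb_truth(man, fx, moi_mode="high", seed=seed + 1)
    data = syn.simulate_perturbseq(truth, n_cells=n_cells, seed=seed + 2)
    fits = fit_all_sgrnas(data.sgrnas, seed=seed + 3)
    table = assign_sgrnas(data.sgrnas, fits, mode="high")
    per_cell = table.per_cell_counts().reindex(data.sgrnas.obs_names).fillna(0)
    return {
        "true_median_moi": float(np.median(data.infections.sum(axis=1))),
        "assigned_median_moi": float(per_cell.median()),
    }


# ---------------------------------------------------------------------------
# cis calibration type-I error
# ---------------------------------------------------------------------------

def cis_null_type_i(seed: int = 80, n_sgrnas: int = 110, n_cells: int = 4000) -> dict:
    """Null high-MOI Perturb-seq run through assignment, per-sgRNA LRT and the
    gene-specific empirical-null calibration; type-I error at p < 0.05 over
    the <= 100 kb pair universe."""
    from .perturb_de import calibrate_cis, de_all_sgrnas, filter_genes_by_detection
    from .sc_assign import assign_sgrnas, fit_all_sgrnas

    fx = syn.generate_genome_fixture(seed=1)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_sgrnas):
        h = fx.hdels.iloc[i % len(fx.hdels)]
        mid = (h.start + h.end) // 2
        rows.append((f"sg{i}", "G" + "".join(rng.choice(list("ACGT"), 19)),
                     "hdel", h.chrom, mid - 10, mid + 10, h["name"]))
    man = pd.DataFrame(
        rows, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
    )
    truth = syn.make_perturb_truth(man, fx, moi_mode="high", seed=seed + 1)
    data = syn.simulate_perturbseq(truth, n_cells=n_cells, seed=seed + 2)
    fits = fit_all_sgrnas(data.sgrnas, seed=seed + 3)
    table = assign_sgrnas(data.sgrnas, fits, mode="high")
    genes = filter_genes_by_detection(data.genes)
    de = de_all_sgrnas(genes, table, man.set_index("id"), policy="other")
    info = man.set_index("id")
    info["target_mid"] = ((info["start"] + info["end"]) // 2).astype(int)
    cis = calibrate_cis(de, info, fx.genes)
    in_uni = cis["distance"] <= 100_000
    p_uni = cis.loc[in_uni, "p"].dropna()
    type_i = float((p_uni < 0.05).mean())
    mc_sd = float(np.sqrt(0.05 * 0.95 / len(p_uni)))
    return {
        "type_i_at_0.05": type_i,
        "mc_sd": mc_sd,
        "n_universe_pairs": int(len(p_uni)),
        "distal_pairs_with_q": int(cis.loc[cis["distance"] > 100_000, "q"].notna().sum()),
        "ks_p_null_uniform": float(
            sps.kstest(cis.loc[~in_uni, "p"].dropna(), "uniform").pvalue
        ),
    }


# ---------------------------------------------------------------------------
# planted-window recovery
# ---------------------------------------------------------------------------

def planted_window_recovery(
    seed: int = 0, n_hdels: int = 2020, n_planted: int = 20,
    guides_per_hdel: int = 10, lfc: float = -1.5,
) -> dict:
    """The headline end-to-end experiment: 20 planted 250-bp proliferation
    windows among 2000 nulls, recovered by both aggregators at q < 0.1.

    Study conditions mirror the deep screen: two individuals with two
    technical replicates each (paired design), 1000x depth, NB dispersion
    0.05.
    """
    rows_h, rows_m = [], []
    for i in range(n_hdels):
        start = i * 1000
        rows_h.append(("chr1", start, start + 250, f"h{i:04d}"))
        for j in range(guides_per_hdel):
            s = start + 12 + j * (226 // guides_per_hdel)
            rows_m.append(
                (f"h{i:04d}_g{j}", "G" * 20, "hdel", "chr1", s, s + 20, f"h{i:04d}")
            )
    hdels = pd.DataFrame(rows_h, columns=["chrom", "start", "end", "name"])
    man = pd.DataFrame(
        rows_m, columns=["id", "spacer", "category", "chrom", "start", "end", "hdel_id"]
    )
    step = max(n_hdels // n_planted, 1)  # spread planted hDels out
    planted = [f"h{i:04d}" for i in range(0, n_hdels, step)][:n_planted]
    hix = hdels.set_index("name")
    intervals = [
        (GenomicInterval("chr1", int(hix.loc[h, "start"]), int(hix.loc[h, "end"])), lfc)
        for h in planted
    ]
    truth = syn.make_screen_truth(
        man, planted=intervals, depth=1000, dispersion=0.05,
        n_replicates=2, n_individuals=2, seed=seed,
    )
    counts = syn.simulate_screen(man, truth, seed=seed + 1)
    stats = ss.fit_nb_glm(counts, design=("individual", "time"))
    wmap = ss.assign_windows(man, hdels, ss.WindowScheme(250, 250, 5))
    rra = ss.alpha_rra(wmap, stats, ss.RraConfig(0.05, 10_000, seed=seed + 2))
    stf = ss.stouffer_windows(wmap, stats, seed=seed + 3)
    out = {"n_planted": len(planted)}
    for name, res in (("rra", rra), ("stouffer", stf)):
        hit = res[res["q"] < 0.1]
        tp = int(hit["hdel_id"].isin(planted).sum())
        out[f"{name}_recovered"] = tp
        out[f"{name}_false"] = int(len(hit) - tp)
    return out


# ---------------------------------------------------------------------------
# enrichment checks
# ---------------------------------------------------------------------------

def enrichment_expectation(seed: int = 6, n_sets: int = 1000) -> dict:
    """Mean null intersection versus the uniform-placement expectation, and
    the per-base bitmap oracle for intersection_bp."""
    from .feature_enrichment import BlockConfig, block_resample

    sizes = {"chr1": 100_000, "chr2": 100_000}
    focal = as_interval_frame(
        [("chr1", i, i + 400) for i in range(500, 60_000, 6000)]
    )
    other = as_interval_frame(
        [(c, i, i + 1000) for c in sizes for i in range(0, 99_000, 5000)]
    )
    cfg = BlockConfig(block_length=2000, n_sets=n_sets, seed=seed)
    nulls = block_resample(focal, sizes, None, cfg)
    null_bp = np.array([intersection_bp(n, other) for n in nulls])
    expected = total_bp(focal) * total_bp(other) / sum(sizes.values())
    mc_sd = float(null_bp.std(ddof=1) / np.sqrt(len(null_bp)))

    # bitmap oracle on a random pair of interval sets
    rng = np.random.default_rng(seed)
    a = [("chr1", int(s), int(s) + int(l)) for s, l in
         zip(rng.integers(0, 90_000, 30), rng.integers(1, 3000, 30))]
    b = [("chr1", int(s), int(s) + int(l)) for s, l in
         zip(rng.integers(0, 90_000, 30), rng.integers(1, 3000, 30))]
    bits_a = np.zeros(100_000, dtype=bool)
    bits_b = np.zeros(100_000, dtype=bool)
    for _, s, e in a:
        bits_a[s:e] = True
    for _, s, e in b:
        bits_b[s:e] = True
    return {
        "null_mean_bp": float(null_bp.mean()),
        "expected_bp": float(expected),
        "mc_sd": mc_sd,
        "bitmap_match": int(intersection_bp(a, b) == int((bits_a & bits_b).sum())),
    }


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def exclusion_rule_checks() -> dict:
    """Boundary behaviour of the homopolymer and abundance exclusion rules."""
    spacers = {
        "g4_at_9": "ACTGACTG" + "GGGG" + "ACTGACTG",
        "c4_at_11": "ACTGACTGAC" + "CCCC" + "ACTGAC",
        "g4_at_2": "AGGGGTACGTACGTACGTAC",
        "clean_lo": "GACTGACTGACTGACTGACT",
        "clean_hi": "GTCAGTCAGTCAGTCAGTCA",
    }
    man = pd.DataFrame({"id": list(spacers), "spacer": list(spacers.values())})
    stats = pd.DataFrame({
        "log2fc": [0.0, 0.0, 0.0, 1.5, 1.5],
        "t0_percentile": [50.0, 50.0, 50.0, 5.0, 5.1],
    }, index=list(spacers))
    out = ss.apply_screen_exclusions(man, stats)
    return {
        "g4_at_9_excluded": int(out.loc["g4_at_9", "excluded"]),
        "c4_at_11_excluded": int(out.loc["c4_at_11", "excluded"]),
        "g4_at_2_retained": int(not out.loc["g4_at_2", "excluded"]),
        "fifth_percentile_excluded": int(out.loc["clean_lo", "excluded"]),
        "above_fifth_retained": int(not out.loc["clean_hi", "excluded"]),
    }
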