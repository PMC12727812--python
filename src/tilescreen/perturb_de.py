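"""Pseudobulk differential expression and cis/trans target mapping.

Per sgRNA, UMIs are summed over assigned cells within each GEM well
(+sgRNA pseudobulk) against a reference pseudobulk (non-targeting cells in
the low-MOI design; all other cells minus same-target cells in the high-MOI
design). Each gene is tested by a likelihood-ratio test between NB GLMs
~well + group and ~well. Cis calling divides each pair's log2 fold-change
by its standard error and standardizes against a gene-specific empirical
null built from sgRNAs targeting loci >= 100 kb away; BH adjustment runs
only over the <= 100 kb pair universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import sparse, stats

from .screen_stats import LOG2, MIN_DISPERSION, benjamini_hochberg, size_factors

UNIVERSE_BP = 100_000


# ---------------------------------------------------------------------------
# pseudobulk
# ---------------------------------------------------------------------------

@dataclass
class PseudobulkCounts:
    """Gene x (group, GEM well) integer sums for one sgRNA contrast."""

    counts: pd.DataFrame  # columns MultiIndex (group, well); group in {target, reference}
    sgrna: str
    n_target_cells: int
    n_reference_cells: int


def filter_genes_by_detection(genes_adata, min_cell_fraction: float = 0.10):
    """Drop genes detected in fewer than the given fraction of cells.

    Applied to the cell-level matrix before any pseudobulking.
    """
    X = genes_adata.X
    det = (
        np.asarray((X > 0).sum(axis=0)).ravel()
        if sparse.issparse(X)
        else (X > 0).sum(axis=0)
    )
    keep = det >= min_cell_fraction * genes_adata.n_obs
    return genes_adata[:, keep].copy()


def _sum_cells(genes_adata, barcodes) -> pd.Series:
    sub = genes_adata[genes_adata.obs_names.isin(barcodes)]
    X = sub.X
    tot = np.asarray(X.sum(axis=0)).ravel() if sparse.issparse(X) else X.sum(axis=0)
    return pd.Series(tot.astype(np.int64), index=genes_adata.var_names)


def reference_cells(
    assignment, sgrna: str, policy: str, sgrna_info: pd.DataFrame
) -> pd.Index:
    """Reference cell set for one sgRNA under the given policy.

    'nontargeting': cells assigned a non-targeting control sgRNA.
    'other': every other retained cell, excluding cells carrying any sgRNA
    that targets the same hDel.
    """
    tab = assignment.assignments
    tab = tab[tab["cell"].isin(assignment.cells)]
    target_cells = set(tab.loc[tab["sgrna"] == sgrna, "cell"])
    if policy == "nontargeting":
        nt = sgrna_info.index[sgrna_info["category"] == "non-targeting"]
        ref = set(tab.loc[tab["sgrna"].isin(nt), "cell"]) - target_cells
    elif policy == "other":
        hdel = sgrna_info.loc[sgrna, "hdel_id"]
        same = sgrna_info.index[
            (sgrna_info["hdel_id"] == hdel) & (sgrna_info["hdel_id"] != "")
        ]
        carriers = set(tab.loc[tab["sgrna"].isin(same), "cell"])
        ref = set(assignment.cells) - carriers - target_cells
    else:
        raise ValueError("policy must be 'nontargeting' or 'other'")
    return pd.Index(sorted(ref))


def pseudobulk(
    genes_adata,
    assignment,
    sgrna: str | None = None,
    policy: str = "nontargeting",
    sgrna_info: pd.DataFrame | None = None,
    target_cells: pd.Index | None = None,
) -> PseudobulkCounts:
    """Exact per-(group, GEM well) UMI sums for one sgRNA contrast.

    ``target_cells`` may be passed directly (e.g. all cells of one hDel's
    sgRNAs pooled for trans profiling); otherwise the cells assigned
    ``sgrna`` are used.
    """
    tab = assignment.assignments
    tab = tab[tab["cell"].isin(assignment.cells)]
    if target_cells is None:
        target_cells = pd.Index(sorted(set(tab.loc[tab["sgrna"] == sgrna, "cell"])))
    label = sgrna or "pooled"
    if len(target_cells) == 0:
        raise ValueError(f"sgRNA {label} has no assigned cells")
    ref = reference_cells(assignment, sgrna, policy, sgrna_info) if sgrna else (
        pd.Index(sorted(set(assignment.cells) - set(target_cells)))
    )
    wells = genes_adata.obs["gem_well"]
    cols = {}
    for group, cells in (("target", pd.Index(target_cells)), ("reference", ref)):
        for well in sorted(wells.unique()):
            in_well = genes_adata.obs_names[wells == well]
            members = cells.intersection(in_well)
            if len(members):
                cols[(group, well)] = _sum_cells(genes_adata, members)
    counts = pd.DataFrame(cols)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["group", "well"])
    return PseudobulkCounts(counts, label, len(target_cells), len(ref))


# ---------------------------------------------------------------------------
# LRT differential expression
# ---------------------------------------------------------------------------

def _trend_shrink(alpha_raw: np.ndarray, mu: np.ndarray) -> np.ndarray:
    a = np.clip(alpha_raw, MIN_DISPERSION, None)
    ok = mu > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, a[ok], rcond=None)
    trend = np.clip(coef[0] + coef[1] / np.clip(mu, 1e-8, None), MIN_DISPERSION, None)
    return np.clip(np.exp(0.5 * np.log(a) + 0.5 * np.log(trend)), MIN_DISPERSION, None)


def de_test(pb: PseudobulkCounts) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of group given GEM well.

    Full model ~well + group versus reduced ~well, sharing a per-gene
    dispersion estimated from Pearson-style residuals of a Poisson fit of
    the full model and shrunk toward a 1/mu trend. Returns log2fc, se
    (group coefficient), and the chi-square(1) LRT p-value.
    """
    counts = pb.counts
    groups = counts.columns.get_level_values("group")
    wells = counts.columns.get_level_values("well")
    if len(np.unique(wells)) < 2:
        raise ValueError("need >= 2 GEM wells for the well covariate")
    cols = [np.ones(counts.shape[1])]
    names = ["intercept"]
    for lev in sorted(np.unique(wells))[1:]:
        cols.append((wells == lev).astype(float))
        names.append(f"well[{lev}]")
    X_red = np.column_stack(cols)
    X_full = np.column_stack(cols + [(groups == "target").astype(float)])
    names_full = names + ["group"]
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        diag = np.abs(np.diag(np.linalg.qr(X_full, mode="r")))
        bad = names_full[int(np.argmin(diag))]
        raise ValueError(f"rank-deficient design: collinear term {bad!r}")

    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    mat = counts.to_numpy(dtype=float)
    n_genes = mat.shape[0]

    # residual method-of-moments dispersion from a Poisson full-model fit
    alpha_raw = np.zeros(n_genes)
    mu_bar = (mat / sf.to_numpy()[None, :]).mean(axis=1)
    fitted = np.zeros_like(mat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_genes):
            try:
                res = sm.GLM(mat[i], X_full, family=sm.families.Poisson(), offset=offset).fit()
                fitted[i] = res.fittedvalues
            except Exception:
                fitted[i] = np.clip(mat[i].mean(), 1e-8, None)
        denom = np.square(fitted).sum(axis=1)
        alpha_raw = np.clip(
            ((np.square(mat - fitted) - fitted).sum(axis=1)) / np.clip(denom, 1e-12, None),
            MIN_DISPERSION, None,
        )
    alpha = _trend_shrink(alpha_raw, mu_bar)

    out = np.full((n_genes, 3), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_genes):
            y = mat[i]
            if y.sum() == 0:
                continue
            fam = sm.families.NegativeBinomial(alpha=float(alpha[i]))
            try:
                full = sm.GLM(y, X_full, family=fam, offset=offset).fit(maxiter=100)
                red = sm.GLM(y, X_red, family=fam, offset=offset).fit(maxiter=100)
            except Exception:
                continue
            lr = max(red.deviance - full.deviance, 0.0)
            coef, se = full.params[-1], full.bse[-1]
            if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
                continue
            out[i] = (coef / LOG2, se / LOG2, stats.chi2.sf(lr, df=1))
    df = pd.DataFrame(out, columns=["log2fc", "se", "p_lrt"], index=counts.index)
    df.index.name = "gene"
    return df


def de_all_sgrnas(
    genes_adata,
    assignment,
    sgrna_info: pd.DataFrame,
    policy: str = "nontargeting",
    sgrnas=None,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Run the per-sgRNA LRT for each (testable) sgRNA; long-format result."""
    tab = assignment.assignments
    tab = tab[tab["cell"].isin(assignment.cells)]
    counts_per = tab.groupby("sgrna").size()
    if sgrnas is None:
        sgrnas = [
            s for s in sgrna_info.index
            if sgrna_info.loc[s, "category"] != "non-targeting"
            and counts_per.get(s, 0) >= min_cells
        ]
    frames = []
    for sg in sgrnas:
        if counts_per.get(sg, 0) == 0:
            warnings.warn(f"sgRNA {sg} has no assigned cells; skipped")
            continue
        pb = pseudobulk(genes_adata, assignment, sg, policy, sgrna_info)
        res = de_test(pb).reset_index()
        res.insert(0, "sgrna", sg)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cis calibration
# ---------------------------------------------------------------------------

def pair_distances(
    de_stats: pd.DataFrame, sgrna_info: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """|protospacer midpoint - TSS| per pair; inf across chromosomes."""
    ginfo = genes.set_index("gene_id") if "gene_id" in genes else genes
    mid = sgrna_info["target_mid"] if "target_mid" in sgrna_info else (
        (sgrna_info["start"] + sgrna_info["end"]) // 2
    )
    s_chrom = de_stats["sgrna"].map(sgrna_info["chrom"])
    g_chrom = de_stats["gene"].map(ginfo["chrom"])
    d = (
        de_stats["sgrna"].map(mid).astype(float)
        - de_stats["gene"].map(ginfo["tss"]).astype(float)
    ).abs()
    return d.where(s_chrom == g_chrom, np.inf)


def calibrate_cis(
    de_stats: pd.DataFrame,
    sgrna_info: pd.DataFrame,
    genes: pd.DataFrame,
    universe_bp: int = UNIVERSE_BP,
    min_null_pairs: int = 50,
) -> pd.DataFrame:
    """Gene-specific empirical-null standardization of per-pair t-statistics.

    t = log2fc / se. Each gene's null is the t of its pairs with sgRNAs
    targeting >= ``universe_bp`` away; z = (t - null mean) / null sd with
    two-sided normal p. BH runs only over pairs within ``universe_bp``;
    distal pairs carry no q. Genes with fewer than ``min_null_pairs`` null
    pairs or zero null sd are flagged and receive no p.
    """
    out = de_stats.copy()
    out["distance"] = pair_distances(out, sgrna_info, genes).to_numpy()
    out["t"] = out["log2fc"] / out["se"]
    out["z"] = np.nan
    out["p"] = np.nan
    out["flagged_gene"] = False
    for gene, sub in out.groupby("gene"):
        null_t = sub.loc[(sub["distance"] >= universe_bp), "t"].dropna()
        if len(null_t) < min_null_pairs or float(null_t.std(ddof=1)) == 0:
            out.loc[sub.index, "flagged_gene"] = True
            continue
        m, s = float(null_t.mean()), float(null_t.std(ddof=1))
        z = (sub["t"] - m) / s
        out.loc[sub.index, "z"] = z
        out.loc[sub.index, "p"] = 2.0 * stats.norm.sf(np.abs(z))
    in_universe = out["distance"] <= universe_bp
    out["q"] = np.nan
    out.loc[in_universe, "q"] = benjamini_hochberg(out.loc[in_universe, "p"])
    return out


# ---------------------------------------------------------------------------
# trans profiling
# ---------------------------------------------------------------------------

def trans_profile(
    genes_adata,
    assignment,
    sgrna_info: pd.DataFrame,
    hdel_id: str,
    policy: str = "nontargeting",
    fdr: float = 0.1,
    per_sgrna_stats: pd.DataFrame | None = None,
) -> dict:
    """Genome-wide DE for one hDel with its sgRNAs pooled into one +group.

    Returns the pooled per-gene table with BH q, the q < fdr hit list with
    directions, and (when per-sgRNA stats are supplied) the inter-sgRNA
    log2fc correlation matrix over the hit genes.
    """
    sgs = sgrna_info.index[sgrna_info["hdel_id"] == hdel_id]
    if not len(sgs):
        raise KeyError(f"no sgRNAs target {hdel_id}")
    tab = assignment.assignments
    tab = tab[tab["cell"].isin(assignment.cells)]
    cells = pd.Index(sorted(set(tab.loc[tab["sgrna"].isin(sgs), "cell"])))
    first = sgs[0]
    ref = reference_cells(assignment, first, policy, sgrna_info)
    ref = ref.difference(cells)
    wells = genes_adata.obs["gem_well"]
    cols = {}
    for group, cset in (("target", cells), ("reference", ref)):
        for well in sorted(wells.unique()):
            members = cset.intersection(genes_adata.obs_names[wells == well])
            if len(members):
                cols[(group, well)] = _sum_cells(genes_adata, members)
    counts = pd.DataFrame(cols)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["group", "well"])
    pb = PseudobulkCounts(counts, f"{hdel_id}:pooled", len(cells), len(ref))

    res = de_test(pb)
    res["q"] = benjamini_hochberg(res["p_lrt"])
    hits = res[res["q"] < fdr].copy()
    hits["direction"] = np.where(hits["log2fc"] < 0, "down", "up")

    corr = None
    if per_sgrna_stats is not None and len(hits):
        sub = per_sgrna_stats[
            per_sgrna_stats["sgrna"].isin(sgs)
            & per_sgrna_stats["gene"].isin(hits.index)
        ]
        wide = sub.pivot(index="gene", columns="sgrna", values="log2fc")
        if wide.shape[1] >= 2:
            corr = wide.corr()
    return {"table": res, "hits": hits, "correlation": corr, "pseudobulk": pb}
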