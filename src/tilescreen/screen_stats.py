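"""Screen count statistics: per-sgRNA NB tests and windowed aggregation.

The per-sgRNA engine is a negative-binomial log-link GLM with median-of-ratios
size factors as offsets and a method-of-moments dispersion shrunk toward a
1/mu trend. Window-level calls combine sgRNA evidence either by alpha-robust
rank aggregation (Beta order-statistic probabilities of the best rank
percentiles below a data-driven alpha, against a permutation null) or by
Stouffer's Z, each followed by Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import polygamma, psi
from statsmodels.stats.multitest import multipletests

LOG2 = np.log(2.0)
MIN_DISPERSION = 1e-8
EXHAUSTIVE_NULL_LIMIT = 4096


@dataclass
class ScreenCounts:
    """sgRNA x sample count matrix with sample metadata."""

    counts: pd.DataFrame  # index: sgRNA id; columns: sample names
    samples: pd.DataFrame  # sample, timepoint, replicate, individual

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValueError("count columns must match sample sheet order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up BH with monotonicity enforcement; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# normalization and dispersion
# ---------------------------------------------------------------------------

def size_factors(counts, control_ids=None) -> pd.Series:
    """DESeq-style median-of-ratios size factors, geometric mean rescaled to 1.

    When ``control_ids`` is given the medians are taken over the control
    features only (control normalization).
    """
    mat = counts.counts if isinstance(counts, ScreenCounts) else counts
    sub = mat.loc[control_ids] if control_ids is not None else mat
    x = sub.to_numpy(dtype=float)
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValueError("no feature with all-positive counts for normalization")
    x = x[pos]
    log_geo = np.mean(np.log(x), axis=1)
    ratios = np.log(x) - log_geo[:, None]
    s = np.exp(np.median(ratios, axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=mat.columns)


def estimate_dispersions(
    counts: pd.DataFrame, sf: pd.Series, groups: pd.Series | np.ndarray
) -> pd.Series:
    """Per-feature NB dispersion: within-group method of moments shrunk on the
    log scale toward a fitted alpha(mu) = a0 + a1/mu trend.

    The shrinkage weight is set empirically: the spread of log MoM values
    around the trend is decomposed into the known chi-square sampling
    variance (trigamma(d/2) at d residual degrees of freedom) plus a
    between-feature prior variance, and each feature's estimate gets the
    usual normal-normal precision weight. With the few samples of a typical
    screen and homogeneous true dispersion the trend dominates, keeping null
    Wald z calibrated; genuinely heterogeneous dispersions retain weight."""
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    groups = np.asarray(groups)
    mu = norm.mean(axis=1)
    num = np.zeros(len(counts))
    den = 0.0
    for g in np.unique(groups):
        cols = groups == g
        if cols.sum() < 2:
            continue
        m = norm[:, cols].mean(axis=1)
        v = norm[:, cols].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        num += (cols.sum() - 1) * a
        den += cols.sum() - 1
    if den == 0:
        raise ValueError("need at least one group with >= 2 samples")
    a_mom = np.clip(num / den, MIN_DISPERSION, None)

    # trend alpha(mu) = a0 + a1/mu by least squares on the raw MoM values
    ok = mu > 0
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, a_mom[ok], rcond=None)
    a_trend = np.clip(coef[0] + coef[1] / np.clip(mu, 1e-8, None), MIN_DISPERSION, None)

    # E[log of a chi^2_d/d-scaled variance estimate] undershoots the truth by
    # psi(d/2) - log(d/2), with sampling variance trigamma(d/2); left
    # uncorrected the bias deflates dispersions and inflates Wald z
    log_bias = psi(den / 2.0) - np.log(den / 2.0)
    s2 = float(polygamma(1, den / 2.0))
    resid = np.log(a_mom) - log_bias - np.log(a_trend)
    spread = float(1.4826 * np.median(np.abs(resid - np.median(resid)))) ** 2
    prior_var = max(spread - s2, 1e-4)
    w = prior_var / (prior_var + s2)
    alpha = np.exp(w * (np.log(a_mom) - log_bias) + (1.0 - w) * np.log(a_trend))
    return pd.Series(np.clip(alpha, MIN_DISPERSION, None), index=counts.index)


# ---------------------------------------------------------------------------
# per-sgRNA GLM
# ---------------------------------------------------------------------------

def _design_matrix(samples: pd.DataFrame, covariates) -> tuple:
    """Intercept + dummy columns; the time indicator is the tested coefficient."""
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        if cov == "time":
            cols.append((samples["timepoint"] == "tfinal").to_numpy(float))
            names.append("time")
        else:
            levels = sorted(samples[cov].unique())
            for lev in levels[1:]:
                cols.append((samples[cov] == lev).to_numpy(float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix with covariates {covariates} is rank deficient")
    return X, names


def fit_nb_glm(
    counts: ScreenCounts,
    design=("time",),
    sf: pd.Series | None = None,
    control_ids=None,
    dispersion: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-sgRNA NB GLM Wald test on the time coefficient.

    Returns one row per sgRNA: log2fc, se, wald_z, two-sided p, BH q,
    one-sided tail p-values, t0 abundance percentile, and an excluded flag
    for non-converged fits.
    """
    if sf is None:
        sf = size_factors(counts, control_ids)
    samples = counts.samples
    if dispersion is None:
        key = samples["timepoint"].astype(str)
        for cov in design:
            if cov != "time":
                key = key + "|" + samples[cov].astype(str)
        dispersion = estimate_dispersions(counts.counts, sf, key.to_numpy())

    X, names = _design_matrix(samples, design)
    t_idx = names.index("time")
    offset = np.log(sf.loc[samples["sample"]].to_numpy())
    mat = counts.counts.to_numpy(dtype=float)

    t0_cols = (samples["timepoint"] == "t0").to_numpy()
    t0_mean = (mat[:, t0_cols] / sf.to_numpy()[None, t0_cols]).mean(axis=1)
    t0_pct = 100.0 * stats.rankdata(t0_mean, method="average") / len(t0_mean)

    n = mat.shape[0]
    out = {
        "log2fc": np.full(n, np.nan), "se": np.full(n, np.nan),
        "wald_z": np.full(n, np.nan), "p": np.full(n, np.nan),
        "p_depleted": np.full(n, np.nan), "p_enriched": np.full(n, np.nan),
        "excluded": np.zeros(n, dtype=bool),
    }
    reasons = [""] * n
    alphas = dispersion.loc[counts.counts.index].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            y = mat[i]
            if y.sum() == 0:
                out["excluded"][i] = True
                reasons[i] = "all_zero"
                continue
            fam = (
                sm.families.Poisson()
                if alphas[i] <= MIN_DISPERSION
                else sm.families.NegativeBinomial(alpha=float(alphas[i]))
            )
            try:
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
                coef, se = res.params[t_idx], res.bse[t_idx]
                if not (np.isfinite(coef) and np.isfinite(se) and se > 0):
                    raise ValueError("non-finite estimate")
            except Exception:
                out["excluded"][i] = True
                reasons[i] = "nonconvergence"
                continue
            z = coef / se
            out["log2fc"][i] = coef / LOG2
            out["se"][i] = se / LOG2
            out["wald_z"][i] = z
            out["p"][i] = 2.0 * stats.norm.sf(abs(z))
            out["p_depleted"][i] = stats.norm.cdf(z)
            out["p_enriched"][i] = stats.norm.sf(z)

    df = pd.DataFrame(out, index=counts.counts.index)
    df.index.name = "id"
    df["reason"] = reasons
    df["t0_percentile"] = t0_pct
    df["q"] = benjamini_hochberg(df["p"].where(~df["excluded"]))
    return df


# ---------------------------------------------------------------------------
# exclusion rules
# ---------------------------------------------------------------------------

def apply_screen_exclusions(
    manifest: pd.DataFrame,
    sgrna_stats: pd.DataFrame,
    enriched_lfc: float = 1.0,
    low_abundance_percentile: float = 5.0,
) -> pd.DataFrame:
    """Post-hoc sgRNA exclusions for off-target and abundance artifacts.

    A guide is excluded iff its spacer contains a GGGG starting at 1-based
    position >= 6, a CCCC starting at positions 10-12, or it is enriched
    (log2fc >= 1) from low initial abundance (t0 mean normalized count at or
    below the 5th percentile).
    """
    spacers = manifest.set_index("id")["spacer"]
    idx = sgrna_stats.index
    reason = pd.Series("", index=idx)
    excl = pd.Series(False, index=idx)

    def motif_positions(spacer, motif):
        return [i + 1 for i in range(len(spacer) - len(motif) + 1)
                if spacer[i:i + len(motif)] == motif]

    for sg in idx:
        sp = spacers.get(sg, "")
        if any(pos >= 6 for pos in motif_positions(sp, "GGGG")):
            excl[sg], reason[sg] = True, "G4_after_position_5"
        elif any(10 <= pos <= 12 for pos in motif_positions(sp, "CCCC")):
            excl[sg], reason[sg] = True, "C4_position_10_12"

    low = (
        (sgrna_stats["log2fc"] >= enriched_lfc)
        & (sgrna_stats["t0_percentile"] <= low_abundance_percentile)
    )
    newly = low & ~excl
    reason[newly] = "enriched_low_abundance"
    excl |= low.fillna(False)
    return pd.DataFrame({"excluded": excl, "reason": reason})


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowScheme:
    size: int = 500
    step: int = 250
    min_guides: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.size):
            raise ValueError("require 0 < step <= size")


def assign_windows(
    manifest: pd.DataFrame,
    hdels: pd.DataFrame,
    scheme: WindowScheme,
    flank_extent: int = 0,
) -> pd.DataFrame:
    """Per-hDel genomic windows and their member sgRNAs.

    Windows start at the hDel start (extended by ``flank_extent`` when flank
    guides are in play), step by ``scheme.step``, and the last window is
    clipped at the hDel end. A guide joins every window containing its
    protospacer midpoint; windows with fewer than ``min_guides`` members are
    dropped. Returns a long table (window_id, hdel_id, chrom, start, end,
    sgrna).
    """
    targeting = manifest.dropna(subset=["chrom", "start", "end"])
    rows = []
    for _, h in hdels.iterrows():
        lo = int(h["start"]) - flank_extent
        hi = int(h["end"]) + flank_extent
        guides = targeting[
            (targeting["hdel_id"] == h["name"]) if "hdel_id" in targeting else
            (targeting["chrom"] == h["chrom"])
        ]
        mid = ((guides["start"] + guides["end"]) // 2).to_numpy()
        for ws in range(lo, hi, scheme.step):
            we = min(ws + scheme.size, hi)
            if we <= ws:
                continue
            member = guides["id"].to_numpy()[(mid >= ws) & (mid < we)]
            if len(member) < scheme.min_guides:
                continue
            wid = f"{h['name']}:{ws}-{we}"
            rows.extend((wid, h["name"], h["chrom"], ws, we, sg) for sg in member)
    return pd.DataFrame(
        rows, columns=["window_id", "hdel_id", "chrom", "start", "end", "sgrna"]
    )


# ---------------------------------------------------------------------------
# alpha-RRA
# ---------------------------------------------------------------------------

@dataclass
class RraConfig:
    alpha_fdr: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1000:
            raise ValueError("n_permutations must be >= 1000")


def _rho_from_sorted(u: np.ndarray, alpha: float) -> np.ndarray:
    """rho for rows of sorted percentiles: min over selected (u <= alpha) of
    BetaCDF(u_(i); i, n - i + 1); 1 when nothing is selected."""
    if u.ndim == 1:
        u = u[None, :]
    n = u.shape[1]
    i = np.arange(1, n + 1)
    bc = stats.beta.cdf(u, i[None, :], n - i[None, :] + 1)
    bc = np.where(u <= alpha, bc, np.inf)
    rho = bc.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def _tail_alpha(tail_p: np.ndarray, alpha_fdr: float) -> tuple:
    """Percentiles of all guides plus the data-driven selection threshold:
    the percentile of the worst guide with tail BH-FDR below ``alpha_fdr``."""
    order = np.argsort(tail_p, kind="mergesort")
    n = len(tail_p)
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    u = rank / n
    q = benjamini_hochberg(tail_p)
    sig = q < alpha_fdr
    alpha = float(u[sig].max()) if sig.any() else 0.0
    return u, alpha


def alpha_rra(
    window_map: pd.DataFrame, sgrna_stats: pd.DataFrame, cfg: RraConfig | None = None
) -> pd.DataFrame:
    """Window-level alpha-RRA for both tails with a permutation null.

    Percentiles come from ranking all included sgRNAs by tail p-value; the
    null draws window-sized percentile sets uniformly (with replacement)
    from the empirical grid {1/N, ..., 1}. The reported window statistic is
    the tail (depletion or enrichment) with the smaller BH q, with the
    alphamean effect (mean log2fc of the selected guides).
    """
    cfg = cfg or RraConfig()
    included = sgrna_stats[~sgrna_stats["excluded"]]
    windows = window_map[window_map["sgrna"].isin(included.index)]
    meta = windows.drop_duplicates("window_id").set_index("window_id")
    members = windows.groupby("window_id")["sgrna"].apply(list)

    results = {}
    rng = np.random.default_rng(cfg.seed)
    N = len(included)
    grid = np.arange(1, N + 1) / N
    for tail in ("depleted", "enriched"):
        tail_p = included[f"p_{tail}"].to_numpy()
        u_all, alpha = _tail_alpha(tail_p, cfg.alpha_fdr)
        u_series = pd.Series(u_all, index=included.index)

        rho_obs, n_guides, effects = {}, {}, {}
        for wid, sgs in members.items():
            u = np.sort(u_series.loc[sgs].to_numpy())
            rho_obs[wid] = float(_rho_from_sorted(u, alpha)[0])
            n_guides[wid] = len(sgs)
            sel = u_series.loc[sgs] <= alpha
            effects[wid] = (
                float(included.loc[sel[sel].index, "log2fc"].mean()) if sel.any() else np.nan
            )

        # permutation null per distinct window size; tiny pools are enumerated
        # exhaustively (all N**n ordered draws) for an exact p
        null_by_n = {}
        for nn in sorted(set(n_guides.values())):
            if N ** nn <= EXHAUSTIVE_NULL_LIMIT:
                draws = np.array(list(itertools.product(grid, repeat=nn)))
            else:
                draws = rng.choice(grid, size=(cfg.n_permutations, nn), replace=True)
            draws.sort(axis=1)
            null_by_n[nn] = np.sort(_rho_from_sorted(draws, alpha))

        rows = []
        for wid, sgs in members.items():
            nn = n_guides[wid]
            null = null_by_n[nn]
            worse = np.searchsorted(null, rho_obs[wid], side="right")
            p = (1.0 + worse) / (1.0 + len(null))
            rows.append((wid, nn, rho_obs[wid], p, effects[wid]))
        df = pd.DataFrame(
            rows, columns=["window_id", "n_guides", "rho", "p", "effect"]
        ).set_index("window_id")
        df["q"] = benjamini_hochberg(df["p"])
        df["degenerate_alpha"] = alpha == 0.0
        results[tail] = df

    dep, enr = results["depleted"], results["enriched"]
    pick_dep = dep["q"].to_numpy() <= enr["q"].to_numpy()
    best = dep.where(pd.Series(pick_dep, index=dep.index), enr)
    out = meta[["hdel_id", "chrom", "start", "end"]].join(best)
    out["direction"] = np.where(pick_dep, "depleted", "enriched")
    out["rho_depleted"], out["p_depleted"], out["q_depleted"] = dep["rho"], dep["p"], dep["q"]
    out["rho_enriched"], out["p_enriched"], out["q_enriched"] = enr["rho"], enr["p"], enr["q"]
    return out.sort_index()


# ---------------------------------------------------------------------------
# Stouffer
# ---------------------------------------------------------------------------

def stouffer_windows(
    window_map: pd.DataFrame,
    sgrna_stats: pd.DataFrame,
    standardize: bool = True,
    null: str = "resample",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Stouffer's method per window: Z = sum(z_i) / sqrt(n), BH across windows.

    Guide-level Wald z are first robustly standardized (median/MAD across
    all included sgRNAs) unless ``standardize=False``. With
    ``null="resample"`` (default) the two-sided p compares |Z| against
    window-sized resamples of the observed guide z pool — an empirical null
    that, like the rank-aggregation permutation null, stays calibrated when
    few screen samples leave the Wald z slightly off N(0,1). With
    ``null="normal"`` p comes from the standard normal reference.
    """
    included = sgrna_stats[~sgrna_stats["excluded"]].copy()
    if standardize:
        z_all = included["wald_z"].to_numpy()
        mad = 1.4826 * np.nanmedian(np.abs(z_all - np.nanmedian(z_all)))
        if mad > 0:
            included["wald_z"] = (z_all - np.nanmedian(z_all)) / mad
    windows = window_map[window_map["sgrna"].isin(included.index)]
    meta = windows.drop_duplicates("window_id").set_index("window_id")
    members = windows.groupby("window_id")["sgrna"]

    rows = []
    for wid, sgs in members:
        z = included.loc[sgs, "wald_z"].to_numpy()
        Z = z.sum() / np.sqrt(len(z))
        rows.append((wid, len(z), Z, float(included.loc[sgs, "log2fc"].mean())))
    df = pd.DataFrame(
        rows, columns=["window_id", "n_guides", "stouffer_z", "effect"]
    ).set_index("window_id")

    if null == "normal":
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["stouffer_z"]))
    elif null == "resample":
        rng = np.random.default_rng(seed)
        pool = included["wald_z"].to_numpy()
        pool = pool[np.isfinite(pool)]
        p = np.empty(len(df))
        for nn in np.unique(df["n_guides"]):
            draws = rng.choice(pool, size=(n_resamples, int(nn)), replace=True)
            null_Z = np.sort(np.abs(draws.sum(axis=1)) / np.sqrt(nn))
            sel = df["n_guides"].to_numpy() == nn
            obs = np.abs(df.loc[sel, "stouffer_z"].to_numpy())
            geq = len(null_Z) - np.searchsorted(null_Z, obs, side="left")
            p[sel] = (1.0 + geq) / (1.0 + n_resamples)
        df["p"] = p
    else:
        raise ValueError("null must be 'resample' or 'normal'")
    df["q"] = benjamini_hochberg(df["p"])
    df["direction"] = np.where(df["stouffer_z"] <= 0, "depleted", "enriched")
    return meta[["hdel_id", "chrom", "start", "end"]].join(df).sort_index()


# ---------------------------------------------------------------------------
# homopolymer diagnostics
# ---------------------------------------------------------------------------

def homopolymer_enrichment(
    manifest: pd.DataFrame,
    sgrna_stats: pd.DataFrame,
    fdr: float = 0.05,
    min_group: int = 10,
    bases: tuple = ("A", "G", "C"),
) -> pd.DataFrame:
    """Significance rate per (homopolymer base, spacer start position) group.

    Runs on ALL tested sgRNAs (diagnostic; exclusion masks are not applied).
    Fold = group significant fraction / overall significant fraction.
    """
    from .guide_library import annotate_homopolymers

    stats_df = sgrna_stats[~sgrna_stats["excluded"]]
    sig = (stats_df["q"] < fdr)
    overall = float(sig.mean()) if len(sig) else np.nan
    spacers = manifest.set_index("id")["spacer"]
    groups: dict = {}
    for sg in stats_df.index:
        for base, start, _length in annotate_homopolymers(spacers.get(sg, "")):
            if base in bases:
                groups.setdefault((base, start), []).append(sg)
    rows = []
    for (base, start), ids in sorted(groups.items()):
        frac = float(sig.loc[ids].mean())
        fold = frac / overall if overall and overall > 0 else np.nan
        rows.append((base, start, len(ids), frac, fold, len(ids) < min_group))
    return pd.DataFrame(
        rows, columns=["base", "position", "n_guides", "frac_significant", "fold", "small_group"]
    )
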