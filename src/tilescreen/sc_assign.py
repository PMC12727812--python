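"""Cell QC and sgRNA-to-cell assignment.

Each sgRNA's capture counts across cells are modeled as a two-component
mixture: ambient background Poisson(lambda) on raw counts versus a true-
expression component, a Gaussian on log2 counts discretized onto the
positive integers (see :mod:`tilescreen.distributions`). The mixture is fit
per sgRNA by EM; a cell is assigned the sgRNA when its posterior probability
of the signal component exceeds 0.5.

The (mu, sigma) M-step has no closed form under discretization, so the
update first tries the responsibility-weighted log2 moments and falls back
to a short Nelder-Mead maximization of the expected complete log-likelihood;
parameters are only ever replaced by values that do not decrease it, which
makes the observed-data log-likelihood provably non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats

from .distributions import log2_gaussian_logpmf

_EPS_RATE = 1e-3


@dataclass
class QcConfig:
    """Cell-level QC thresholds; percentiles are realized on the input matrix."""

    gene_percentile: float = 10.0
    umi_percentile: float = 10.0
    mito_max: float = 0.15
    mito_min: float | None = None  # high-MOI mode uses 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.gene_percentile <= 100 and 0 <= self.umi_percentile <= 100):
            raise ValueError("percentiles must be in [0, 100]")
        if self.mito_min is not None and not (0 <= self.mito_min < self.mito_max <= 1):
            raise ValueError("require 0 <= mito_min < mito_max <= 1")


def qc_filter_cells(genes_adata, qc: QcConfig | None = None, thresholds: dict | None = None):
    """Remove cells failing ANY criterion; returns (kept barcodes, thresholds).

    Floors are the matrix's own percentiles of genes-detected and total UMIs;
    a cell is removed when strictly below a floor, strictly above the
    mitochondrial maximum, or (when configured) strictly below the
    mitochondrial minimum. Passing previously realized ``thresholds`` applies
    them as-is instead of recomputing percentiles, making filtering
    idempotent.
    """
    qc = qc or QcConfig()
    X = genes_adata.X
    if X.shape[0] == 0:
        raise ValueError("empty matrix")
    if sparse.issparse(X):
        genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
        umis = np.asarray(X.sum(axis=1)).ravel()
        mito_mask = genes_adata.var["mito"].to_numpy().astype(bool)
        mito_umis = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    else:
        genes_detected = (X > 0).sum(axis=1)
        umis = X.sum(axis=1)
        mito_umis = X[:, genes_adata.var["mito"].to_numpy().astype(bool)].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umis > 0, mito_umis / np.maximum(umis, 1), 1.0)

    if thresholds is None:
        thresholds = {
            "gene_floor": float(np.percentile(genes_detected, qc.gene_percentile)),
            "umi_floor": float(np.percentile(umis, qc.umi_percentile)),
            "mito_max": qc.mito_max,
            "mito_min": qc.mito_min,
        }
    fail = (
        (genes_detected < thresholds["gene_floor"])
        | (umis < thresholds["umi_floor"])
        | (mito_frac > thresholds["mito_max"])
    )
    if thresholds.get("mito_min") is not None:
        fail |= mito_frac < thresholds["mito_min"]
    kept = genes_adata.obs_names[~fail]
    return kept, thresholds


# ---------------------------------------------------------------------------
# mixture model
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Fitted two-component Poisson / discretized-log2-Gaussian mixture."""

    sgrna: str
    lam: float
    mu: float
    sigma: float
    pi: float
    loglik: float
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    degenerate: bool = False
    n_iter: int = 0


def _mixture_loglik(values, weights, lam, mu, sigma, pi):
    la = stats.poisson.logpmf(values, lam)
    lb = log2_gaussian_logpmf(values, mu, sigma)
    m = np.maximum(la, lb)
    with np.errstate(divide="ignore"):
        mix = m + np.log(
            (1.0 - pi) * np.exp(la - m) + pi * np.exp(lb - m)
        )
    return float((weights * mix).sum())


def fit_sgrna_mixture(
    counts,
    seed: int = 0,
    max_iter: int = 250,
    tol: float = 1e-6,
    sigma_floor: float = 0.05,
    n_restarts: int = 3,
    sgrna: str = "",
) -> MixtureFit:
    """EM fit of the capture mixture for one sgRNA's counts across cells.

    Initialization: lambda from counts at or below the median, (mu, sigma)
    from log2 counts above the 90th percentile, pi as the fraction above it.
    Converged when the relative log-likelihood change drops below ``tol``;
    on non-convergence up to ``n_restarts`` seeded jittered re-inits are
    tried and the best final log-likelihood kept. An all-zero vector yields
    a degenerate fit (pi = 0) rather than an error.
    """
    c = np.asarray(counts).ravel()
    if c.ndim != 1 or len(c) < 20:
        raise ValueError("need a vector of counts over >= 20 cells")
    if c.max() == 0:
        return MixtureFit(sgrna, _EPS_RATE, np.nan, sigma_floor, 0.0,
                          loglik=0.0, degenerate=True)

    values, inverse = np.unique(c, return_inverse=True)
    weights = np.bincount(inverse).astype(float)

    med = np.median(c)
    p90 = np.percentile(c, 90)
    hi = c[c > p90]
    lam0 = max(float(c[c <= med].mean()) if (c <= med).any() else 0.0, _EPS_RATE)
    if hi.size:
        mu0 = float(np.log2(hi).mean()) if (hi >= 1).all() else float(np.log2(np.maximum(hi, 1)).mean())
        s0 = max(float(np.log2(np.maximum(hi, 1)).std()), sigma_floor)
        pi0 = float((c > p90).mean())
    else:
        mu0, s0, pi0 = float(np.log2(max(c.max(), 2))), 1.0, 0.01

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(1 + n_restarts):
        if attempt == 0:
            lam, mu, sigma, pi = lam0, mu0, s0, pi0
        else:
            lam = max(lam0 * np.exp(0.3 * rng.standard_normal()), _EPS_RATE)
            mu = mu0 + rng.standard_normal()
            sigma = max(s0 * np.exp(0.3 * rng.standard_normal()), sigma_floor)
            pi = float(np.clip(pi0 * np.exp(0.5 * rng.standard_normal()), 1e-4, 0.999))
        fit = _em(values, weights, lam, mu, sigma, pi, max_iter, tol, sigma_floor)
        fit.sgrna = sgrna
        if best is None or fit.loglik > best.loglik:
            best = fit
        if best.converged:
            break
    return best


def _em(values, weights, lam, mu, sigma, pi, max_iter, tol, sigma_floor) -> MixtureFit:
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    log2v = np.log2(np.maximum(values, 1.0))
    for it in range(1, max_iter + 1):
        # E-step
        la = stats.poisson.logpmf(values, lam)
        lb = log2_gaussian_logpmf(values, mu, sigma)
        with np.errstate(divide="ignore"):
            num = np.log(max(pi, 1e-300)) + lb
            den = np.logaddexp(np.log(max(1 - pi, 1e-300)) + la, num)
        r = np.exp(num - den)
        r = np.where(values < 1, 0.0, r)  # zero counts carry no signal mass

        # M-step: exact for pi and lambda
        wr = weights * r
        w1 = weights - wr
        pi = float(wr.sum() / weights.sum())
        lam = max(float((w1 * values).sum() / max(w1.sum(), 1e-12)), _EPS_RATE)

        # (mu, sigma): weighted log2 moments, falling back to direct ascent
        if wr.sum() > 0:
            def q2(theta):
                m, ls = theta
                return -(wr * log2_gaussian_logpmf(values, m, max(np.exp(ls), sigma_floor))).sum()

            cur = -q2((mu, np.log(sigma)))
            m_c = float((wr * log2v).sum() / wr.sum())
            s_c = max(
                float(np.sqrt((wr * (log2v - m_c) ** 2).sum() / wr.sum())), sigma_floor
            )
            if -q2((m_c, np.log(s_c))) >= cur:
                mu, sigma = m_c, s_c
            else:
                res = optimize.minimize(
                    q2, x0=(mu, np.log(sigma)), method="Nelder-Mead",
                    options={"maxiter": 80, "xatol": 1e-5, "fatol": 1e-9},
                )
                if -res.fun > cur:
                    mu, sigma = float(res.x[0]), max(float(np.exp(res.x[1])), sigma_floor)

        ll = _mixture_loglik(values, weights, lam, mu, sigma, pi)
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
            converged = True
            prev = ll
            break
        prev = ll
    return MixtureFit("", lam, mu, sigma, pi, loglik=prev,
                      loglik_trace=trace, converged=converged, n_iter=it)


def posterior_signal(fit: MixtureFit, counts) -> np.ndarray:
    """Posterior probability of the signal component per cell."""
    c = np.asarray(counts, dtype=float).ravel()
    if fit.degenerate or fit.pi <= 0:
        return np.zeros(len(c))
    la = stats.poisson.logpmf(c, fit.lam)
    lb = log2_gaussian_logpmf(c, fit.mu, fit.sigma)
    num = np.log(fit.pi) + lb
    den = np.logaddexp(np.log(max(1 - fit.pi, 1e-300)) + la, num)
    post = np.exp(num - den)
    return np.where(c < 1, 0.0, post)


def fit_all_sgrnas(sgrna_adata, seed: int = 0, **kwargs) -> dict:
    """Fit the capture mixture for every sgRNA column; seeds are derived
    deterministically per sgRNA."""
    X = sgrna_adata.X
    fits = {}
    for j, name in enumerate(sgrna_adata.var_names):
        col = np.asarray(X[:, j].todense()).ravel() if sparse.issparse(X) else X[:, j]
        fits[name] = fit_sgrna_mixture(col, seed=seed + j, sgrna=name, **kwargs)
    return fits


@dataclass
class AssignmentTable:
    """Cell-sgRNA assignments (posterior > 0.5) plus the retained cell set."""

    assignments: pd.DataFrame  # cell, sgrna, posterior
    mode: str  # low | high
    cells: pd.Index  # cells usable downstream under the MOI mode

    def per_cell_counts(self) -> pd.Series:
        return self.assignments.groupby("cell").size()


def assign_sgrnas(sgrna_adata, fits: dict, mode: str = "low") -> AssignmentTable:
    """Assign sgRNAs to cells at posterior > 0.5 (strict).

    Low-MOI mode restricts the downstream cell set to cells with exactly one
    assignment; high-MOI mode keeps every cell with at least one.
    """
    if mode not in ("low", "high"):
        raise ValueError("mode must be 'low' or 'high'")
    X = sgrna_adata.X
    rows = []
    barcodes = np.asarray(sgrna_adata.obs_names)
    for j, name in enumerate(sgrna_adata.var_names):
        col = np.asarray(X[:, j].todense()).ravel() if sparse.issparse(X) else X[:, j]
        post = posterior_signal(fits[name], col)
        hit = post > 0.5
        rows.extend(zip(barcodes[hit], [name] * int(hit.sum()), post[hit]))
    table = pd.DataFrame(rows, columns=["cell", "sgrna", "posterior"])
    per_cell = table.groupby("cell").size()
    if mode == "low":
        cells = pd.Index(per_cell[per_cell == 1].index)
    else:
        cells = pd.Index(per_cell[per_cell >= 1].index)
    return AssignmentTable(assignments=table, mode=mode, cells=cells)
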