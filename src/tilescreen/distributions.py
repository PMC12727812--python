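"""Discrete count distributions shared by the simulator and the assignment model.

The sgRNA-capture signal component is a Gaussian on log2 scale discretized onto
the positive integers: a count c >= 1 receives the Gaussian probability mass
between log2(max(c - 0.5, 0.25)) and log2(c + 0.5), renormalized over c >= 1.
Because consecutive bin edges coincide (upper edge of c is the lower edge of
c + 1), the normalizer is 1 - Phi((log2(0.5) - mu) / sigma) in closed form, and
zero counts carry no signal mass. This makes the generator and the mixture
fitter share one proper probability law on integers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

_LOG2_HALF = -1.0  # log2(0.5), lower edge of the c = 1 bin

_TINY = 1e-300


def log2_gaussian_pmf(counts, mu: float, sigma: float) -> np.ndarray:
    """Probability mass of the discretized log2-Gaussian at integer counts.

    Counts < 1 get exactly zero mass.
    """
    c = np.asarray(counts, dtype=float)
    upper = (np.log2(np.maximum(c, 1.0) + 0.5) - mu) / sigma
    lower = (np.log2(np.maximum(np.maximum(c, 1.0) - 0.5, 0.25)) - mu) / sigma
    z = 1.0 - stats.norm.cdf((_LOG2_HALF - mu) / sigma)
    z = max(z, _TINY)
    pmf = (stats.norm.cdf(upper) - stats.norm.cdf(lower)) / z
    pmf = np.where(c >= 1, np.maximum(pmf, 0.0), 0.0)
    return pmf


def log2_gaussian_logpmf(counts, mu: float, sigma: float) -> np.ndarray:
    return np.log(np.maximum(log2_gaussian_pmf(counts, mu, sigma), _TINY))


def sample_log2_gaussian(rng: np.random.Generator, mu: float, sigma: float, size: int) -> np.ndarray:
    """Draw integer counts >= 1 from the discretized log2-Gaussian.

    Inverse-CDF sampling: draw the latent Gaussian truncated below the c = 1
    bin edge, then snap to the integer whose [c - 0.5, c + 0.5) linear-scale
    bin contains 2**x — exactly the pmf above.
    """
    lo = stats.norm.cdf((_LOG2_HALF - mu) / sigma)
    u = rng.uniform(lo, 1.0, size=size)
    x = mu + sigma * stats.norm.ppf(u)
    c = np.floor(np.exp2(x) + 0.5)
    return np.maximum(c, 1.0).astype(np.int64)


def sample_negative_binomial(
    rng: np.random.Generator, mean, dispersion
) -> np.ndarray:
    """NB draws parameterized by mean mu and dispersion alpha (var = mu + alpha mu^2).

    alpha = 0 falls back to Poisson.
    """
    mu = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        a = alpha[~pois]
        m = mu[~pois]
        n = 1.0 / a
        p = n / (n + m)
        out[~pois] = rng.negative_binomial(n, p)
    return out
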