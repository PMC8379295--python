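"""MCMC convergence diagnostics and posterior summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PosteriorChains

__all__ = [
    "gelman_rubin",
    "chain_autocorrelation",
    "posterior_summary",
    "qq_envelope",
]


def _chain_matrix(chains, parameter) -> np.ndarray:
    if isinstance(chains, PosteriorChains):
        return np.asarray(chains.by_chain(parameter), dtype=float)
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a (n_chains, n_draws) array")
    return x


def gelman_rubin(chains, parameter: str | None = None) -> tuple[float, float]:
    """Potential scale reduction factor R-hat and its upper 97.5% bound.

    Classic between/within-chain variance-ratio estimator with the
    degrees-of-freedom correction; the upper bound replaces the
    between-chain term by its 97.5% F-quantile.  Values near 1 indicate the
    chains sample the same distribution.  ``chains`` may be a
    :class:`~cyclessm.inference.PosteriorChains` (with ``parameter``) or a
    raw (n_chains, n_draws) array.
    """
    x = _chain_matrix(chains, parameter)
    m, n = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains; run multiple chains")
    if n < 10:
        raise ValueError("need >= 10 saved draws per chain")
    means = x.mean(axis=1)
    vars_ = x.var(axis=1, ddof=1)
    W = vars_.mean()
    B = n * means.var(ddof=1)
    if B == 0 or W == 0:
        return 1.0, 1.0
    var_w = vars_.var(ddof=1) / m
    muhat = means.mean()
    cov_wx2 = np.cov(vars_, means ** 2, ddof=1)[0, 1]
    cov_wx = np.cov(vars_, means, ddof=1)[0, 1]
    cov_wb = (n / m) * (cov_wx2 - 2.0 * muhat * cov_wx)
    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B / n
    var_V = ((n - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * (2.0 / (m - 1)) * B ** 2
             + 2 * (n - 1) * (1 + 1 / m) * cov_wb) / n ** 2
    df = max(2.0 * V ** 2 / var_V, 1e-8) if var_V > 0 else np.inf
    df_adj = (df + 3) / (df + 1) if np.isfinite(df) else 1.0
    r2_fixed = (n - 1) / n
    r2_rand = (1 + 1 / m) * B / (n * W)
    rhat = float(np.sqrt(df_adj * (r2_fixed + r2_rand)))
    df_w = 2.0 * W ** 2 / var_w if var_w > 0 else np.inf
    fq = stats.f.ppf(0.975, m - 1, df_w) if np.isfinite(df_w) else 1.0
    upper = float(np.sqrt(df_adj * (r2_fixed + fq * r2_rand)))
    return rhat, upper


def chain_autocorrelation(chains, parameter: str | None = None,
                          max_lag: int = 50) -> np.ndarray:
    """Sample autocorrelation of the saved draws, averaged across chains.

    Lag 0 is 1 by definition; for well-thinned chains the remaining lags
    should sit inside the white-noise band ±3/sqrt(n).
    """
    x = _chain_matrix(chains, parameter)
    m, n = x.shape
    if n < max_lag + 1:
        raise ValueError(f"need > {max_lag} draws per chain for max_lag={max_lag}")
    acfs = np.zeros((m, max_lag + 1))
    for c in range(m):
        xc = x[c] - x[c].mean()
        denom = float(xc @ xc)
        if denom == 0:
            acfs[c, 0] = 1.0
            continue
        for lag in range(max_lag + 1):
            acfs[c, lag] = float(xc[: n - lag] @ xc[lag:]) / denom
    return acfs.mean(axis=0)


def posterior_summary(chains: PosteriorChains) -> pd.DataFrame:
    """Posterior mean, SE and equal-tailed 95% interval per parameter.

    The SE column is the posterior standard deviation (the spread of the
    estimate); mc_se is the batch-means Monte-Carlo standard error of the
    posterior mean.
    """
    rows = []
    for name in chains.parameter_names:
        d = chains.draws(name)
        n = d.size
        nb = min(30, max(2, n // 10))
        batches = np.array_split(d, nb)
        mc_se = float(np.std([b.mean() for b in batches], ddof=1) / np.sqrt(nb))
        lo, hi = np.quantile(d, [0.025, 0.975])
        rows.append({
            "parameter": name,
            "mean": float(d.mean()),
            "se": float(d.std(ddof=1)) if n > 1 else 0.0,
            "mc_se": mc_se,
            "q2.5": float(lo),
            "q97.5": float(hi),
        })
    return pd.DataFrame(rows).set_index("parameter")


def qq_envelope(residuals, n_sim: int = 99, level: float = 0.95,
                seed: int = 0):
    """Normal Q-Q check with simulated envelopes.

    Standardises the residuals, sorts them, and compares each order
    statistic against the pointwise ``level`` band across ``n_sim``
    simulated standard-normal samples of the same size.  Returns
    ``(lower, upper, outside_fraction)``; for genuinely Gaussian residuals
    the outside fraction is about 1 - level, while heavy-tailed random
    effects push most points outside the band.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size < 3:
        raise ValueError("need at least 3 residuals")
    if n_sim < 19:
        raise ValueError("n_sim must be >= 19 for a meaningful envelope")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals are constant")
    z = np.sort((r - r.mean()) / sd)
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_sim, r.size)), axis=1)
    a = (1.0 - level) / 2.0
    lower = np.quantile(sims, a, axis=0)
    upper = np.quantile(sims, 1.0 - a, axis=0)
    outside = float(np.mean((z < lower) | (z > upper)))
    return lower, upper, outside
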