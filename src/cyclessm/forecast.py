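"""Posterior predictive forecasts of upcoming cycle lengths.

For each saved posterior draw the Kalman filter is run over a woman's
observed cycles conditional on that draw's parameters and overdispersion
history, giving the Gaussian moments of the next (standard) cycle; the
posterior predictive is then the mixture over draws, with a fresh
Bernoulli(pi) overdispersion event inflating the variance of non-standard
future cycles.  One-step intervals are computed from the exact mixture CDF
(deterministic given the draws); multi-step forecasts sample forward paths.

The future covariate offset defaults to zero — next cycle's symptoms are
unknown at forecast time — with a carry-forward-last-cycle option.  The
point forecast is the posterior predictive mean.  Intervals are
equal-tailed and nested across levels by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .inference import PosteriorChains
from .statespace import _build_system, _predict_from_state, _run_filter

__all__ = ["ForecastResult", "predictive_distribution", "forecast_cohort",
           "forecast_error"]

DEFAULT_LEVELS = (0.80, 0.95, 0.99)


@dataclass
class ForecastResult:
    """Point forecast, nested interval set and predictive draws."""

    woman_id: str
    horizon: int
    point: float
    intervals: dict[float, tuple[float, float]]
    draws: np.ndarray

    def interval(self, level: float) -> tuple[float, float]:
        return self.intervals[level]


def forecast_error(observed: float, result: ForecastResult) -> float:
    """Forecast error: observed minus point forecast (days)."""
    return float(observed) - result.point


def _flat(chains: PosteriorChains, name: str):
    arr = chains.params.get(name)
    if arr is None:
        return None
    return arr.reshape(-1, *arr.shape[2:])


def _mixture_quantile(q, mu, sd0, sd1, pi):
    """Quantile of the equal-weight-over-draws Gaussian mixture."""
    smax = max(sd0.max(), sd1.max() if sd1 is not None else 0.0)
    lo = mu.min() - 12 * smax
    hi = mu.max() + 12 * smax

    if sd1 is None:
        def cdf(x):
            return float(norm.cdf((x - mu) / sd0).mean())
    else:
        def cdf(x):
            c0 = norm.cdf((x - mu) / sd0)
            c1 = norm.cdf((x - mu) / sd1)
            return float(((1 - pi) * c0 + pi * c1).mean())

    return brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-8)


def forecast_cohort(chains: PosteriorChains, indices=None, horizon: int = 1,
                    levels=DEFAULT_LEVELS, n_obs=None, seed: int = 0,
                    future_covariates: str = "zero") -> list[ForecastResult]:
    """Posterior predictive forecasts for several training-cohort women.

    Parameters
    ----------
    indices : sequence of int, optional
        Positional woman indices in the training data (default: all).
    n_obs : int array, optional
        Number of leading cycles to condition on per woman (default: all
        observed cycles).  Used for time-series cross-validation.
    horizon : int
        Steps ahead.  At horizon 1 the intervals are exact mixture
        quantiles; beyond that they are empirical quantiles of sampled
        forward paths.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    spec = chains.spec
    data = chains.data
    if indices is None:
        indices = np.arange(data.n_women)
    indices = np.asarray(indices, dtype=int)
    if indices.size and (indices.min() < 0 or indices.max() >= data.n_women):
        raise IndexError("woman index out of range of the training cohort")
    Nw = indices.size
    J = data.j_max
    lengths = data.lengths[indices]
    if n_obs is None:
        n_obs = lengths
    n_obs = np.broadcast_to(np.asarray(n_obs, dtype=int), (Nw,))
    if np.any(n_obs < 1) or np.any(n_obs > lengths):
        raise ValueError("n_obs must be in [1, observed cycles] per woman")

    D = chains.n_chains * chains.n_saved
    B = Nw * D

    def tile_w(x):  # per-woman array -> batch (women-major)
        return np.repeat(x[indices], D, axis=0)

    def tile_d(x):  # per-draw array -> batch
        return np.tile(x, Nw)

    y_b = tile_w(data.y)
    mask_b = np.arange(J)[None, :] < np.repeat(n_obs, D)[:, None]
    ages_b = tile_w(data.ages) if spec.trend == "lmm_age" else None

    p = {n: _flat(chains, n) for n in
         ("beta0", "beta1", "pi", "phi", "theta", "sigma_eta", "sigma_eps",
          "sigma_w", "sigma_b0", "sigma_b1", "alpha")}
    offset = np.zeros((B, J))
    c_hist = None
    if spec.covariates:
        sel = [data.covariate_names.index(c) for c in spec.covariates]
        counts = data.counts[:, :, sel][indices]           # (Nw, J, K)
        c_hist = np.einsum("njk,dk->ndj", counts, p["alpha"]).reshape(B, J)
        offset += c_hist
    if spec.overdispersion and chains.lam is not None:
        lw = (chains.lam * chains.w).reshape(D, data.n_women, J)
        offset += lw[:, indices, :].transpose(1, 0, 2).reshape(B, J)
    elif spec.overdispersion and chains.lam is None:
        raise ValueError("overdispersion spec requires retained lambda/w draws")
    if spec.trend == "lmm_age":
        offset += tile_d(p["beta0"])[:, None] + tile_d(p["beta1"])[:, None] * ages_b

    bat = {k: (tile_d(v) if v is not None and v.ndim == 1 else None)
           for k, v in p.items()}
    T, RQR, Z, H, a1, P1 = _build_system(
        spec, B, beta0=bat["beta0"], sigma_eta=bat["sigma_eta"],
        sigma_eps=bat["sigma_eps"], phi=bat["phi"], theta=bat["theta"],
        sigma_b0=bat["sigma_b0"], sigma_b1=bat["sigma_b1"], sigma_b01=0.0,
        ages=ages_b)
    _, a_f, P_f = _run_filter(y_b, offset, mask_b, T, RQR, Z, H, a1, P1)

    # future observation geometry
    off_fut = np.zeros((B, horizon))
    if future_covariates == "carry" and c_hist is not None:
        last = c_hist[np.arange(B), np.repeat(n_obs, D) - 1]
        off_fut += last[:, None]
    elif future_covariates not in ("zero", "carry"):
        raise ValueError(f"future_covariates={future_covariates!r}")
    Z_future = None
    Z_pred = Z if Z.ndim == 2 else Z[:, 0, :]
    if spec.trend == "lmm_age":
        last_age = ages_b[np.arange(B), np.repeat(n_obs, D) - 1]
        last_len = y_b[np.arange(B), np.repeat(n_obs, D) - 1]
        fut_ages = last_age[:, None] + (last_len / 365.25)[:, None] * np.arange(
            1, horizon + 1)[None, :]
        off_fut += (tile_d(p["beta0"])[:, None]
                    + tile_d(p["beta1"])[:, None] * fut_ages)
        d = a_f.shape[1]
        Z_future = np.zeros((B, horizon, d))
        Z_future[:, :, 0] = 1.0
        Z_future[:, :, 1] = fut_ages
        if spec.error != "none":
            Z_future[:, :, 2] = 1.0

    pi_d = tile_d(p["pi"]) if spec.overdispersion else None
    sw_d = tile_d(p["sigma_w"]) if spec.overdispersion else None
    rng = np.random.default_rng(seed)
    results: list[ForecastResult] = []

    if horizon == 1:
        means, variances = _predict_from_state(
            a_f, P_f, T, RQR, Z_pred, H, 1, offset_future=off_fut,
            Z_future=Z_future)
        mu = means[:, 0].reshape(Nw, D)
        sd0 = np.sqrt(variances[:, 0]).reshape(Nw, D)
        if spec.overdispersion:
            sd1 = np.sqrt(variances[:, 0] + sw_d ** 2).reshape(Nw, D)
            piw = pi_d.reshape(Nw, D)
            lam_new = rng.random((Nw, D)) < piw
            sd_draw = np.where(lam_new, sd1, sd0)
        else:
            sd1 = piw = None
            sd_draw = sd0
        samp = mu + sd_draw * rng.standard_normal((Nw, D))
        for n, i in enumerate(indices):
            ints = {}
            for lev in sorted(levels):
                a = (1.0 - lev) / 2.0
                lo = _mixture_quantile(a, mu[n], sd0[n],
                                       None if sd1 is None else sd1[n],
                                       None if piw is None else piw[n])
                hi = _mixture_quantile(1.0 - a, mu[n], sd0[n],
                                       None if sd1 is None else sd1[n],
                                       None if piw is None else piw[n])
                ints[lev] = (lo, hi)
            results.append(ForecastResult(
                woman_id=data.woman_ids[i], horizon=1,
                point=float(mu[n].mean()), intervals=ints, draws=samp[n]))
        return results

    # horizon > 1: sample forward paths draw by draw
    d_state = a_f.shape[1]
    L = np.linalg.cholesky(
        P_f + 1e-12 * np.eye(d_state)[None])
    state = a_f + np.einsum("bde,be->bd", L, rng.standard_normal((B, d_state)))
    se_d = tile_d(p["sigma_eps"])
    eta_sd = tile_d(p["sigma_eta"]) if spec.trend == "random_walk" else 0.0
    th_d = tile_d(p["theta"]) if spec.has_ma else None
    paths = np.zeros((B, horizon))
    d_trend = 1 if spec.trend == "random_walk" else 2
    for k in range(horizon):
        state = np.einsum("bde,be->bd", T, state)
        eps_k = se_d * rng.standard_normal(B)
        if spec.trend == "random_walk":
            state[:, 0] += eta_sd * rng.standard_normal(B)
        if spec.error == "ar1":
            state[:, d_trend] += eps_k
        elif spec.error in ("ma1", "arma11"):
            state[:, d_trend] += eps_k
            state[:, d_trend + 1] = th_d * eps_k
        Zk = Z_future[:, k, :] if Z_future is not None else Z_pred
        y_k = np.einsum("bd,bd->b", Zk, state) + off_fut[:, k]
        if spec.error == "none":
            y_k = y_k + se_d * rng.standard_normal(B)
        if spec.overdispersion:
            lam_k = rng.random(B) < pi_d
            y_k = y_k + np.where(lam_k, sw_d * rng.standard_normal(B), 0.0)
        paths[:, k] = y_k
    final = paths[:, -1].reshape(Nw, D)
    for n, i in enumerate(indices):
        ints = {}
        for lev in sorted(levels):
            a = (1.0 - lev) / 2.0
            lo, hi = np.quantile(final[n], [a, 1.0 - a])
            ints[lev] = (float(lo), float(hi))
        results.append(ForecastResult(
            woman_id=data.woman_ids[i], horizon=horizon,
            point=float(final[n].mean()), intervals=ints, draws=final[n]))
    return results


def predictive_distribution(chains: PosteriorChains, woman, horizon: int = 1,
                            levels=DEFAULT_LEVELS, n_obs: int | None = None,
                            seed: int = 0,
                            future_covariates: str = "zero") -> ForecastResult:
    """One woman's posterior predictive forecast (see :func:`forecast_cohort`).

    ``woman`` is a woman_id or positional index; the woman must belong to
    the cohort the chains were fitted on (her overdispersion history is part
    of the posterior draws).
    """
    i = woman if isinstance(woman, (int, np.integer)) else chains.data.index_of(woman)
    res = forecast_cohort(
        chains, indices=[int(i)], horizon=horizon, levels=levels,
        n_obs=None if n_obs is None else [int(n_obs)], seed=seed,
        future_covariates=future_covariates)
    return res[0]
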