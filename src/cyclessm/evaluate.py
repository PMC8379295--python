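"""Forecast metrics, model selection and validation schemes.

Implements the agreement metrics used to compare candidate models — RMSE,
Pearson r, Lin's concordance correlation coefficient (CCC) and its
accuracy factor C_b = CCC / r — together with the modified information
criterion

    BIC = (N - p) log(N sigma_eps^2 / (N - p))
          + p log[(sum_ij y_ij^2 - N sigma_eps^2) / p]

the hold-out-last-cycle validation split, the staged model-selection
procedure (trend, then error structure, then covariates), and the
attrition-aware test-set evaluation by number of observed cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import Cohort, CycleRecord, CycleSeries
from .forecast import forecast_cohort
from .inference import McmcConfig, PosteriorChains, PriorConfig, sample_posterior
from .statespace import ModelSpec

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "ccc",
    "accuracy_cb",
    "bic",
    "parameter_count",
    "HoldoutSplit",
    "holdout_split",
    "MetricsRow",
    "select_model",
    "select_covariates",
    "attrition_evaluation",
    "residual_diagnostics",
    "DEFAULT_SPEC_GRID",
]


def rmse(observed, predicted) -> float:
    """Root mean squared forecast error (days)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if o.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((o - p) ** 2)))


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    2 cov(x, y) / (var x + var y + (mean x - mean y)^2) with population
    (1/n) moments, per the original definition; penalises both scatter and
    location/scale shift, so CCC = r * C_b <= |r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        raise ValueError("CCC undefined for a constant input")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def accuracy_cb(ccc_value: float, r_value: float) -> float:
    """Accuracy (bias-correction) factor C_b = CCC / r."""
    if r_value == 0:
        raise ValueError("C_b undefined when r = 0")
    out = ccc_value / r_value
    if out < 0:
        raise ValueError("CCC and r must share a sign")
    return float(out)


def _ccc_ci(x, y, level: float = 0.95):
    """Asymptotic CI for Lin's CCC via the Fisher z-transform."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    c = ccc(x, y)
    if n < 4 or abs(c) >= 1:
        return (float("nan"), float("nan"))
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0:
        return (float("nan"), float("nan"))
    u = (x.mean() - y.mean()) / np.sqrt(x.std() * y.std())
    c2 = c * c
    r2 = r * r
    se2 = ((1 - r2) * c2 / ((1 - c2) * r2)
           + 2 * c ** 3 * (1 - c) * u * u / (r * (1 - c2) ** 2)
           - c ** 4 * u ** 4 / (2 * r2 * (1 - c2) ** 2)) / (n - 2)
    se2 = max(se2, 0.0)
    z = np.arctanh(c)
    from scipy.stats import norm as _norm
    zc = _norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zc * np.sqrt(se2)), np.tanh(z + zc * np.sqrt(se2))
    return float(lo), float(hi)


def bic(N: int, p: int, sigma_eps_sq: float, sum_y_sq: float) -> float:
    """Modified BIC balancing residual variance against parameter count.

    Requires N > p >= 1 and sum_y_sq > N * sigma_eps_sq so both logarithms
    are defined; strictly increasing in sigma_eps_sq on the valid domain.
    """
    if not (N > p >= 1):
        raise ValueError(f"need N > p >= 1, got N={N}, p={p}")
    if sigma_eps_sq <= 0:
        raise ValueError("sigma_eps_sq must be > 0")
    resid = sum_y_sq - N * sigma_eps_sq
    if resid <= 0:
        raise ValueError(
            f"sum_y_sq ({sum_y_sq:.4g}) must exceed N*sigma_eps_sq "
            f"({N * sigma_eps_sq:.4g}); the second logarithm is undefined")
    return float((N - p) * np.log(N * sigma_eps_sq / (N - p))
                 + p * np.log(resid / p))


#: Parameter counts for the candidate structures (before covariates), as
#: conventionally tabulated: fixed effects + variance components + mixture
#: probability.  Keyed by (trend, error, overdispersion).
_N_PAR = {
    ("random_walk", "none", False): 3,
    ("random_walk", "ar1", False): 4,
    ("random_walk", "ma1", False): 4,
    ("random_walk", "arma11", False): 5,
    ("random_walk", "none", True): 5,
    ("random_walk", "ar1", True): 6,
    ("random_walk", "ma1", True): 6,
    ("random_walk", "arma11", True): 7,
    ("lmm_age", "none", False): 5,
    ("lmm_age", "ar1", False): 6,
    ("lmm_age", "ma1", False): 6,
    ("lmm_age", "arma11", False): 8,
}


def parameter_count(spec: ModelSpec) -> int:
    """Number of parameters entering the BIC for ``spec``."""
    key = (spec.trend, spec.error, spec.overdispersion)
    if key not in _N_PAR:
        raise ValueError(f"no parameter count tabulated for {key}")
    return _N_PAR[key] + len(spec.covariates)


#: The 12 canonical candidate structures for stages 1-2 of selection.
DEFAULT_SPEC_GRID = tuple(
    ModelSpec(trend=t, error=e, overdispersion=o)
    for t, e, o in _N_PAR
)


# ---------------------------------------------------------------------------
# hold-out validation
# ---------------------------------------------------------------------------

@dataclass
class HoldoutSplit:
    """Training cohort with each woman's last cycle held back as test data.

    Women with a single cycle stay training-only.  ``test`` maps woman_id
    to the held-out :class:`CycleRecord`.
    """

    train: Cohort
    test: dict[str, CycleRecord]


def holdout_split(cohort: Cohort) -> HoldoutSplit:
    if cohort.I == 0:
        raise ValueError("cohort is empty")
    train_series = []
    test = {}
    for s in cohort.series:
        if s.n_cycles >= 2:
            train_series.append(CycleSeries(s.woman_id, s.records[:-1]))
            test[s.woman_id] = s.records[-1]
        else:
            train_series.append(s)
    return HoldoutSplit(
        train=Cohort(series=train_series,
                     covariate_names=list(cohort.covariate_names)),
        test=test,
    )


# ---------------------------------------------------------------------------
# staged model selection
# ---------------------------------------------------------------------------

@dataclass
class MetricsRow:
    """One candidate model's scorecard."""

    spec: ModelSpec
    n_params: int
    rmse: float
    ccc: float
    r: float
    c_b: float
    bic: float

    def as_dict(self) -> dict:
        return {
            "model": self.spec.label, "n_params": self.n_params,
            "rmse": self.rmse, "ccc": self.ccc, "r": self.r,
            "c_b": self.c_b, "bic": self.bic,
        }


def _fit_and_score(cohort, spec, prior, mcmc, seed_offset=0) -> tuple[MetricsRow, PosteriorChains]:
    split = holdout_split(cohort)
    chains = sample_posterior(split.train, spec, prior=prior, mcmc=mcmc)
    data = chains.data
    test_idx = [data.index_of(wid) for wid in split.test]
    obs = np.array([split.test[data.woman_ids[i]].length_days for i in test_idx],
                   dtype=float)
    fcs = forecast_cohort(chains, indices=test_idx, horizon=1,
                          seed=mcmc.seed + seed_offset)
    pred = np.array([f.point for f in fcs])
    m_rmse = rmse(obs, pred)
    m_ccc = ccc(obs, pred)
    m_r = float(np.corrcoef(obs, pred)[0, 1])
    sig2 = float(np.mean(chains.draws("sigma_eps") ** 2))
    N = int(data.mask.sum())
    sum_y2 = float((data.y[data.mask] ** 2).sum())
    row = MetricsRow(spec=spec, n_params=parameter_count(spec),
                     rmse=m_rmse, ccc=m_ccc, r=m_r,
                     c_b=accuracy_cb(m_ccc, m_r),
                     bic=bic(N, parameter_count(spec), sig2, sum_y2))
    return row, chains


def select_model(cohort: Cohort, spec_grid=DEFAULT_SPEC_GRID,
                 prior: PriorConfig | None = None,
                 mcmc: McmcConfig | None = None,
                 rmse_tolerance: float = 0.02):
    """Fit every candidate spec and choose by the balance rule.

    Each spec is fitted to the training part of the hold-out split; forecast
    metrics (RMSE, CCC, r, C_b) are computed on the held-back last cycles
    and the BIC on the training fit.  Candidates whose RMSE is within
    ``rmse_tolerance`` (relative) of the best forecaster are eligible, and
    the eligible spec with minimal BIC wins — forecast accuracy first, then
    parsimony of fit.  Failed fits are skipped with a warning.

    Returns ``(table, chosen_spec)`` where ``table`` is a DataFrame in the
    conventional layout, ranked with the chosen spec first.
    """
    prior = prior or PriorConfig()
    mcmc = mcmc or McmcConfig()
    rows: list[MetricsRow] = []
    for k, spec in enumerate(spec_grid):
        try:
            row, _ = _fit_and_score(cohort, spec, prior, mcmc, seed_offset=k)
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - selection must survive one bad fit
            logger.warning("fit failed for %s: %s", spec.label, exc)
    if not rows:
        raise RuntimeError("every candidate fit failed")
    best_rmse = min(r.rmse for r in rows)
    eligible = [r for r in rows if r.rmse <= best_rmse * (1.0 + rmse_tolerance)]
    chosen = min(eligible, key=lambda r: r.bic)
    rows.sort(key=lambda r: (r is not chosen, r.bic))
    table = pd.DataFrame([r.as_dict() for r in rows])
    return table, chosen.spec


def select_covariates(chains: PosteriorChains, candidates=None) -> list[str]:
    """Stage-3 covariate selection by 95% credible interval.

    Retains covariate k iff 0 lies outside the equal-tailed 95% interval of
    its effect alpha_k.
    """
    if "alpha" not in chains.params:
        raise ValueError("chains carry no covariate-effect draws")
    names = list(chains.spec.covariates)
    if candidates is None:
        candidates = names
    kept = []
    for name in candidates:
        if name not in names:
            raise ValueError(f"{name!r} was not a covariate of the fitted spec")
        d = chains.draws(f"alpha[{name}]")
        lo, hi = np.quantile(d, [0.025, 0.975])
        if not (lo <= 0.0 <= hi):
            kept.append(name)
    return kept


# ---------------------------------------------------------------------------
# attrition-aware test evaluation
# ---------------------------------------------------------------------------

def attrition_evaluation(chains: PosteriorChains, test_ids,
                         min_cycles: int = 3, max_cycles: int = 12,
                         seed: int = 0) -> pd.DataFrame:
    """One-step-ahead accuracy by number of observed cycles, under attrition.

    For each scenario n_i in [min_cycles, max_cycles], women in the test
    pool with at least n_i observed cycles have their n_i-th cycle predicted
    from their first n_i - 1; women with fewer cycles drop out of the
    scenario (they remain in the training fit).  Returns one row per
    scenario: N, RMSE, CCC with its 95% CI, r and C_b; empty scenarios get
    N=0 and null metrics.
    """
    data = chains.data
    ids = [data.index_of(w) if not isinstance(w, (int, np.integer)) else int(w)
           for w in test_ids]
    rows = []
    for n_i in range(min_cycles, max_cycles + 1):
        pool = [i for i in ids if data.lengths[i] >= n_i]
        if not pool:
            rows.append({"n_cycles": n_i, "N": 0, "rmse": np.nan,
                         "ccc": np.nan, "ccc_lower": np.nan,
                         "ccc_upper": np.nan, "r": np.nan, "c_b": np.nan})
            continue
        fcs = forecast_cohort(chains, indices=pool, horizon=1,
                              n_obs=[n_i - 1] * len(pool), seed=seed + n_i)
        obs = np.array([data.y[i, n_i - 1] for i in pool])
        pred = np.array([f.point for f in fcs])
        try:
            m_ccc = ccc(obs, pred)
            m_r = float(np.corrcoef(obs, pred)[0, 1])
        except ValueError:  # fewer than two points or a degenerate scenario
            m_ccc = m_r = np.nan
        lo, hi = _ccc_ci(obs, pred) if len(pool) >= 4 else (np.nan, np.nan)
        rows.append({
            "n_cycles": n_i, "N": len(pool), "rmse": rmse(obs, pred),
            "ccc": m_ccc, "ccc_lower": lo, "ccc_upper": hi, "r": m_r,
            "c_b": m_ccc / m_r if m_r else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# residual diagnostics
# ---------------------------------------------------------------------------

def residual_diagnostics(chains: PosteriorChains, max_lag: int = 10) -> dict:
    """Standardised innovation residuals with ACF and an age regression.

    Residuals are the posterior-mean innovations standardised by the
    posterior-mean sigma_eps.  Returns the residual array (masked cells
    NaN), the pooled within-woman residual ACF, and the OLS slope of
    residual on age with its 95% CI — a well-specified fit shows white-noise
    ACF and a slope interval covering zero.
    """
    if chains.mean_eps is None:
        raise ValueError("chains carry no innovation means")
    data = chains.data
    sig = float(np.mean(chains.draws("sigma_eps")))
    std_resid = np.where(data.mask, chains.mean_eps / sig, np.nan)

    # pooled within-woman ACF of the standardised residuals
    acf = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    denom = np.nanvar(std_resid)
    for i in range(data.n_women):
        r = std_resid[i, : int(data.lengths[i])]
        r = r - np.nanmean(r)
        for lag in range(min(max_lag, r.size - 1) + 1):
            acf[lag] += float(r[: r.size - lag] @ r[lag:])
            counts[lag] += r.size - lag
    with np.errstate(invalid="ignore", divide="ignore"):
        acf = (acf / counts) / denom if denom > 0 else acf * np.nan

    flat = std_resid[data.mask]
    ages = data.ages[data.mask]
    ols = sm.OLS(flat, sm.add_constant(ages)).fit()
    lo, hi = ols.conf_int()[1]
    return {
        "std_residuals": std_resid,
        "acf": acf,
        "age_slope": float(ols.params[1]),
        "age_slope_ci": (float(lo), float(hi)),
    }
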