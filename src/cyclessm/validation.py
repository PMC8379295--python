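"""Simulation-based validation studies.

Self-contained study runners used by the test suite and the reproduction
script: likelihood-oracle agreement, parameter-recovery coverage, forecast
interval calibration, overdispersion detection on injected outliers, and
self-consistency of the staged model selection.  Each study simulates its
own data from the reference parameter values, runs the full pipeline, and
returns plain numbers.

Problem sizes default to desk scale (a few hundred women, chains of a
thousand sweeps) so each study completes in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np

from .datamodel import CycleRecord, CycleSeries
from .evaluate import holdout_split, rmse, select_model
from .forecast import forecast_cohort
from .inference import McmcConfig, overdispersion_probability, sample_posterior
from .simulate import CohortDesign, inject_outlier_cycles, reference_parameters, simulate_cohort
from .statespace import (
    ModelSpec,
    ParameterSet,
    dense_loglik,
    kalman_loglik,
)

__all__ = [
    "oracle_agreement_study",
    "recovery_study",
    "calibration_study",
    "detection_study",
    "selection_study",
    "cohort_shape_study",
]

SELECTED_SPEC = ModelSpec("random_walk", "ma1", True, ())

#: covariates retained by the stage-3 rule in the reference analysis
RETAINED_COVARIATES = ("injury", "stomach_cramps", "tender_breasts",
                       "flow_light")

ALL_SPECS = tuple(
    ModelSpec(trend=t, error=e, overdispersion=o, covariates=("s1", "s2"))
    for t in ("random_walk", "lmm_age")
    for e in ("none", "ar1", "ma1", "arma11")
    for o in ((False, True) if t == "random_walk" else (False,))
)


def _random_instance(rng, spec, j_max=10):
    J = int(rng.integers(1, j_max))
    kw = dict(beta0=27 + rng.normal(), sigma_eps=0.5 + rng.random(),
              alpha=tuple(rng.normal(0, 0.2, 2)))
    if spec.trend == "random_walk":
        kw["sigma_eta"] = 0.5 + rng.random()
    else:
        kw.update(beta1=-0.1 + 0.1 * rng.normal(), sigma_b0=0.5 + rng.random(),
                  sigma_b1=0.05 + 0.1 * rng.random())
    if spec.has_ar:
        kw["phi"] = rng.uniform(-0.8, 0.8)
    if spec.has_ma:
        kw["theta"] = rng.uniform(-0.9, 0.9)
    if spec.overdispersion:
        kw.update(pi=rng.random(), sigma_w=3 + rng.random())
    params = ParameterSet(**kw)
    recs = [CycleRecord("x", j + 1, int(rng.integers(24, 32)), 30 + j * 0.08,
                        tuple(int(v) for v in rng.integers(0, 4, 2)))
            for j in range(J)]
    series = CycleSeries("x", recs)
    lam = (rng.random(J) < 0.3).astype(float) if spec.overdispersion else None
    w = rng.normal(0, 3, J) if spec.overdispersion else None
    return series, params, lam, w


def oracle_agreement_study(n_instances: int = 200, seed: int = 0):
    """Max |Kalman loglik - dense MVN loglik| over random small instances
    spanning all 12 candidate structures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    k = 0
    while k < n_instances:
        for spec in ALL_SPECS:
            series, params, lam, w = _random_instance(rng, spec)
            diff = abs(kalman_loglik(series, spec, params, lam, w)
                       - dense_loglik(series, spec, params, lam, w))
            worst = max(worst, diff)
            k += 1
            if k >= n_instances:
                break
    return worst, n_instances


def recovery_study(n_reps: int = 5, n_women: int = 300, seed: int = 0,
                   cycles_range=(4, 12)):
    """Credible-interval coverage of the true parameters over seeded
    replicates of the selected model (trend, mixture, MA and the retained
    covariate effects)."""
    spec = ModelSpec("random_walk", "ma1", True, RETAINED_COVARIATES)
    params = reference_parameters(spec)
    truthvals = {"beta0": params.beta0, "pi": params.pi, "theta": params.theta,
                 "sigma_eta": params.sigma_eta, "sigma_w": params.sigma_w,
                 "sigma_eps": params.sigma_eps}
    for k, name in enumerate(spec.covariates):
        truthvals[f"alpha[{name}]"] = params.alpha[k]
    ss = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2 ** 31)
    hits = {k: 0 for k in truthvals}
    for rep in range(n_reps):
        cohort, _ = simulate_cohort(
            CohortDesign(n_women=n_women, cycles_range=cycles_range),
            params, spec, seed=int(ss[2 * rep]))
        chains = sample_posterior(
            cohort, spec, mcmc=McmcConfig(seed=int(ss[2 * rep + 1])),
            retain_latent=False)
        for name, v in truthvals.items():
            lo, hi = np.quantile(chains.draws(name), [0.025, 0.975])
            hits[name] += int(lo <= v <= hi)
    return hits, n_reps


def calibration_study(n_women: int = 500, seed: int = 0, cycles_range=(5, 13)):
    """Empirical coverage of the 80/95/99% one-step forecast intervals on
    held-out last cycles of a well-specified simulation, plus the hold-out
    RMSE."""
    spec = SELECTED_SPEC
    params = reference_parameters(spec)
    ss = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    cohort, _ = simulate_cohort(
        CohortDesign(n_women=n_women, cycles_range=cycles_range), params,
        spec, seed=int(ss[0]))
    split = holdout_split(cohort)
    chains = sample_posterior(split.train, spec,
                              mcmc=McmcConfig(seed=int(ss[1])))
    data = chains.data
    idx = [data.index_of(wid) for wid in split.test]
    obs = np.array([split.test[data.woman_ids[i]].length_days for i in idx],
                   dtype=float)
    fcs = forecast_cohort(chains, indices=idx, horizon=1, seed=int(ss[2]))
    pred = np.array([f.point for f in fcs])
    out = {"n": len(idx), "rmse": rmse(obs, pred)}
    for lev in (0.8, 0.95, 0.99):
        cov = float(np.mean([
            f.intervals[lev][0] <= o <= f.intervals[lev][1]
            for f, o in zip(fcs, obs)]))
        out[f"coverage_{int(lev * 100)}"] = cov
    return out


def detection_study(n_women: int = 80, seed: int = 0, n_inject: int = 40):
    """Posterior overdispersion probabilities for injected outlier cycles
    (|w| > 4 sigma_eps) versus clean cycles."""
    spec = SELECTED_SPEC
    params = reference_parameters(spec)
    ss = np.random.SeedSequence(seed).generate_state(3) % (2 ** 31)
    cohort, truth = simulate_cohort(
        CohortDesign(n_women=n_women, cycles_range=(8, 12)), params, spec,
        seed=int(ss[0]))
    rng = np.random.default_rng(int(ss[1]))
    cells = []
    step = max(1, n_women // n_inject)
    for i in range(0, n_women, step):
        J = int(truth.mask[i].sum())
        cells.append((i, int(rng.integers(2, J))))
        if len(cells) == n_inject:
            break
    cohort2, truth2 = inject_outlier_cycles(
        cohort, truth, cells, seed=int(ss[1]),
        min_magnitude=4 * params.sigma_eps)
    chains = sample_posterior(cohort2, spec, mcmc=McmcConfig(seed=int(ss[2])))
    p_inj = [overdispersion_probability(chains, i, j) for i, j in cells]
    injected = set(cells)
    clean = [(i, j + 1) for i in range(n_women)
             for j in range(int(truth2.mask[i].sum()))
             if truth2.lam[i, j] == 0 and (i, j + 1) not in injected]
    p_clean = [overdispersion_probability(chains, i, j) for i, j in clean]
    return {"n_injected": len(p_inj), "n_clean": len(p_clean),
            "p_injected": float(np.mean(p_inj)),
            "p_clean": float(np.mean(p_clean))}


def selection_study(n_reps: int = 5, n_women: int = 120, seed: int = 0):
    """Fraction of replicates in which staged selection on data simulated
    from the overdispersed MA(1) model picks a spec with the
    overdispersion term (reduced four-spec grid)."""
    params = reference_parameters(SELECTED_SPEC)
    grid = [ModelSpec("random_walk", e, o, ())
            for o in (False, True) for e in ("none", "ma1")]
    ss = np.random.SeedSequence(seed).generate_state(2 * n_reps) % (2 ** 31)
    n_overd = 0
    for rep in range(n_reps):
        cohort, _ = simulate_cohort(
            CohortDesign(n_women=n_women, cycles_range=(5, 12)), params,
            SELECTED_SPEC, seed=int(ss[2 * rep]))
        _, chosen = select_model(
            cohort, grid,
            mcmc=McmcConfig(n_iter=700, burn_in=350, thin=5,
                            seed=int(ss[2 * rep + 1])))
        n_overd += int(chosen.overdispersion)
    return n_overd, n_reps


def cohort_shape_study(n_women: int = 500, seed: int = 0):
    """Marginal shape of a reference-parameter cohort: mean observed length
    and the percentage of overdispersed cycles."""
    spec = ModelSpec("random_walk", "ma1", True, RETAINED_COVARIATES)
    params = reference_parameters(spec)
    cohort, truth = simulate_cohort(
        CohortDesign(n_women=n_women, cycles_range=(4, 53)), params, spec,
        seed=seed)
    data_mean = float(np.concatenate(
        [s.lengths for s in cohort.series]).mean())
    return {"n_cycles": cohort.n_observations,
            "mean_length_days": data_mean,
            "overdispersed_pct": float(truth.lam[truth.mask].mean() * 100)}
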