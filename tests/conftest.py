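"""Shared fixtures: a reference spec, a small simulated cohort with a fitted
posterior (reused across forecast/evaluation/diagnostic tests), and a random
instance generator for likelihood-oracle checks."""

import pytest

import cyclessm as c


@pytest.fixture(scope="session")
def ref_spec():
    return c.ModelSpec("random_walk", "ma1", True, ())


@pytest.fixture(scope="session")
def ref_params(ref_spec):
    return c.reference_parameters(ref_spec)


@pytest.fixture(scope="session")
def small_sim(ref_spec, ref_params):
    """60 women x 6-10 cycles from the selected model."""
    cohort, truth = c.simulate_cohort(
        c.CohortDesign(n_women=60, cycles_range=(6, 10)), ref_params,
        ref_spec, seed=3)
    return cohort, truth


@pytest.fixture(scope="session")
def small_fit(ref_spec, small_sim):
    cohort, _ = small_sim
    chains = c.sample_posterior(
        cohort, ref_spec,
        mcmc=c.McmcConfig(n_iter=600, burn_in=300, thin=5, seed=4))
    return cohort, chains


ALL_SPECS = tuple(
    c.ModelSpec(trend=t, error=e, overdispersion=o, covariates=("s1", "s2"))
    for t in ("random_walk", "lmm_age")
    for e in ("none", "ar1", "ma1", "arma11")
    for o in ((False, True) if t == "random_walk" else (False,))
)


def random_instance(rng, spec, j_max=10):
    """A random small series + parameter set valid for ``spec``."""
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
    params = c.ParameterSet(**kw)
    recs = [
        c.CycleRecord("x", j + 1, int(rng.integers(24, 32)), 30 + j * 0.08,
                      tuple(int(v) for v in rng.integers(0, 4, 2)))
        for j in range(J)
    ]
    series = c.CycleSeries("x", recs)
    lam = (rng.random(J) < 0.3).astype(float) if spec.overdispersion else None
    w = rng.normal(0, 3, J) if spec.overdispersion else None
    return series, params, lam, w
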