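"""Gibbs sampler correctness and MCMC diagnostics."""

import numpy as np
import pytest
from scipy.signal import lfilter
from scipy.stats import kstest, norm

import cyclessm as c
from cyclessm.datamodel import ConfigurationError, PreparedData
from cyclessm.inference import PriorConfig, _RandomWalkGibbs


def test_prior_only_run_recovers_uniform_pi():
    """With no data every conditional reduces to its prior; pi is Uniform(0,1)."""
    empty = c.Cohort(series=[], covariate_names=[])
    ch = c.sample_posterior(
        empty, c.ModelSpec("random_walk", "none", True, ()),
        mcmc=c.McmcConfig(n_chains=2, n_iter=1200, burn_in=200, thin=1, seed=0),
        retain_latent=False)
    assert kstest(ch.draws("pi"), "uniform").pvalue > 1e-3


def test_identical_seed_reproduces_chains(small_sim, ref_spec):
    cohort, _ = small_sim
    cfg = c.McmcConfig(n_chains=2, n_iter=120, burn_in=60, thin=2, seed=5)
    a = c.sample_posterior(cohort, ref_spec, mcmc=cfg)
    b = c.sample_posterior(cohort, ref_spec, mcmc=cfg)
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    c2 = c.sample_posterior(cohort, ref_spec,
                            mcmc=c.McmcConfig(n_chains=2, n_iter=120, burn_in=60,
                                              thin=2, seed=6))
    assert not np.array_equal(a.params["beta0"], c2.params["beta0"])


def test_unknown_covariate_rejected(small_sim):
    cohort, _ = small_sim
    spec = c.ModelSpec("random_walk", "none", False, ("not_a_symptom",))
    with pytest.raises(ConfigurationError):
        c.sample_posterior(cohort, spec)


def test_lmm_overdispersion_with_arma_not_supported(small_sim):
    cohort, _ = small_sim
    spec = c.ModelSpec("lmm_age", "ma1", True, ())
    with pytest.raises(NotImplementedError):
        c.sample_posterior(cohort, spec)


def test_mixture_update_reduces_to_prior_as_shock_vanishes():
    """As sigma_w -> 0 both mixture components coincide, so the posterior
    overdispersion indicator is a pi-coin whatever the residuals."""
    rng = np.random.default_rng(0)
    I, J = 400, 4
    y = 27 + rng.normal(0, 3, (I, J))
    data = PreparedData(y, np.ones((I, J), bool), np.zeros((I, J)),
                        np.zeros((I, J, 0)), [str(i) for i in range(I)], [])
    g = _RandomWalkGibbs(c.ModelSpec("random_walk", "none", True, ()),
                         PriorConfig(), data)
    st = g.init_state(rng)
    st.update(pi=0.5, sigma_w2=1e-16, sigma_eta2=1.0, sigma_eps2=2.0,
              beta0=27.0)
    fracs = []
    for _ in range(20):
        g._draw_overdispersion(rng, st)
        fracs.append(st["lam"].mean())
    frac = np.mean(fracs)
    se = np.sqrt(0.25 / (I * J * 20))
    assert abs(frac - 0.5) < 4 * se


def test_successive_conditional_simulation_matches_prior():
    """Geweke-style check: alternating forward data simulation with Gibbs
    sweeps must leave the prior invariant (joint-correctness of every
    conditional, including the collapsed mixture block)."""
    I, J = 4, 4
    spec = c.ModelSpec("random_walk", "ma1", True, ())
    prior = PriorConfig(kappa=3.0, mu_ar_prior_var=0.04)
    rng = np.random.default_rng(7)
    n_iter, n_sweeps = 2500, 3

    def prior_draw():
        st = {
            "sigma_beta2": 1.0 / rng.gamma(3.0, 1 / 3.0),
            "mu_beta0": rng.uniform(*prior.beta0_bounds),
            "sigma_eta2": 1.0 / rng.gamma(3.0, 1 / 3.0),
            "sigma_eps2": 1.0 / rng.gamma(3.0, 1 / 3.0),
            "sigma_w2": 1.0 / rng.gamma(3.0, 1 / 3.0),
            "pi": rng.uniform(),
            "sigma_ar2": 1.0 / rng.gamma(3.0, 1 / 3.0),
            "mu_ar": rng.normal(0, 0.2),
            "phi": 0.0, "alpha": np.zeros(0), "phi_scale": 0.1,
        }
        st["beta0"] = rng.normal(st["mu_beta0"], np.sqrt(st["sigma_beta2"]))
        st["theta"] = rng.normal(st["mu_ar"], np.sqrt(st["sigma_ar2"]))
        return st

    def forward(st):
        eps = rng.normal(0, np.sqrt(st["sigma_eps2"]), (I, J))
        gamma = lfilter([1.0, st["theta"]], [1.0, 0.0], eps, axis=1)
        m = st["beta0"] + np.cumsum(
            rng.normal(0, np.sqrt(st["sigma_eta2"]), (I, J)), axis=1)
        lam = (rng.random((I, J)) < st["pi"]).astype(float)
        w = np.where(lam > 0, rng.normal(0, np.sqrt(st["sigma_w2"]), (I, J)), 0.0)
        return m + gamma + lam * w, eps, lam, w

    def stats_of(st):
        return [st["beta0"], st["pi"], st["theta"], np.log(st["sigma_eta2"]),
                np.log(st["sigma_eps2"]), np.log(st["sigma_w2"])]

    mc = np.array([stats_of(prior_draw()) for _ in range(n_iter)])
    st = prior_draw()
    sc = np.zeros((n_iter, 6))
    mask = np.ones((I, J), bool)
    for it in range(n_iter):
        y, eps, lam, w = forward(st)
        data = PreparedData(y, mask, np.zeros((I, J)), np.zeros((I, J, 0)),
                            [str(i) for i in range(I)], [])
        g = _RandomWalkGibbs(spec, prior, data)
        st["eps"], st["lam"], st["w"] = eps, lam, w
        for _ in range(n_sweeps):
            g.sweep(rng, st)
        sc[it] = stats_of(st)

    def batch_se(x, nb=40):
        bs = np.array([b.mean() for b in np.array_split(x, nb)])
        return bs.std(ddof=1) / np.sqrt(nb)

    for k in range(6):
        se = np.sqrt(batch_se(mc[:, k]) ** 2 + batch_se(sc[:, k]) ** 2)
        z = (mc[:, k].mean() - sc[:, k].mean()) / se
        assert abs(z) < 5.0, f"statistic {k}: z={z:.2f}"


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self):
        x = np.tile(np.random.default_rng(0).normal(size=200), (3, 1))
        assert c.gelman_rubin(x) == (1.0, 1.0)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = np.stack([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        rhat, upper = c.gelman_rubin(x)
        assert rhat > 1.5
        assert upper >= rhat

    def test_agrees_with_arviz_when_mixed(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        x = rng.normal(size=(4, 500))
        rhat, _ = c.gelman_rubin(x)
        assert rhat == pytest.approx(float(np.asarray(az.rhat(x))), abs=0.05)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            c.gelman_rubin(np.zeros((1, 100)))


class TestAutocorrelation:
    def test_lag_zero_is_one_and_iid_is_white(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 2000))
        acf = c.chain_autocorrelation(x, max_lag=20)
        assert acf[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf[1:]) < 3 / np.sqrt(2000))

    def test_ar1_chain_acf(self):
        rng = np.random.default_rng(4)
        n = 20000
        e = rng.normal(size=n)
        x = lfilter([1.0], [1.0, -0.9], e)
        acf = c.chain_autocorrelation(x[None, :], max_lag=2)
        assert acf[1] == pytest.approx(0.9, abs=0.03)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            c.chain_autocorrelation(np.zeros((2, 10)), max_lag=50)


class TestPosteriorSummary:
    def test_constant_draws(self, small_sim, ref_spec):
        cohort, _ = small_sim
        ch = c.sample_posterior(cohort, ref_spec,
                               mcmc=c.McmcConfig(n_chains=2, n_iter=60,
                                                 burn_in=30, thin=3, seed=1))
        ch.params["beta0"][:] = 27.0
        row = c.posterior_summary(ch).loc["beta0"]
        assert row["mean"] == 27.0
        assert row["q2.5"] == row["q97.5"] == 27.0

    def test_normal_draws_quantiles(self):
        rng = np.random.default_rng(5)
        empty = c.Cohort(series=[], covariate_names=[])
        ch = c.sample_posterior(
            empty, c.ModelSpec("random_walk", "none", False, ()),
            mcmc=c.McmcConfig(n_chains=2, n_iter=110, burn_in=10, thin=1, seed=0),
            retain_latent=False)
        ch.params["beta0"] = rng.normal(size=(2, 50000))
        row = c.posterior_summary(ch).loc["beta0"]
        assert row["q2.5"] == pytest.approx(-1.96, abs=0.05)
        assert row["q97.5"] == pytest.approx(1.96, abs=0.05)


class TestQqEnvelope:
    def test_gaussian_residuals_sit_mostly_inside(self):
        rng = np.random.default_rng(6)
        fracs = [c.qq_envelope(rng.standard_normal(150), seed=k)[2]
                 for k in range(20)]
        assert 0.0 <= np.mean(fracs) < 0.15

    def test_heavy_tails_escape_the_envelope(self):
        rng = np.random.default_rng(7)
        fracs = [c.qq_envelope(rng.standard_t(2, 150), seed=k)[2]
                 for k in range(10)]
        assert np.mean(fracs) > 0.3

    def test_exact_normal_scores_all_inside(self):
        n = 100
        scores = norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert c.qq_envelope(scores, seed=0)[2] == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            c.qq_envelope([1.0, 2.0])
        with pytest.raises(ValueError):
            c.qq_envelope(np.random.default_rng(0).normal(size=50), n_sim=5)


class TestOverdispersionProbability:
    def test_requires_retained_lambda(self, small_sim, ref_spec):
        cohort, _ = small_sim
        ch = c.sample_posterior(cohort, ref_spec,
                               mcmc=c.McmcConfig(n_chains=2, n_iter=60,
                                                 burn_in=30, thin=3, seed=1),
                               retain_latent=False)
        with pytest.raises(ValueError, match="retain"):
            c.overdispersion_probability(ch, 0, 1)

    def test_probability_in_unit_interval(self, small_fit):
        _, ch = small_fit
        p = c.overdispersion_probability(ch, 0, 2)
        assert 0.0 <= p <= 1.0
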