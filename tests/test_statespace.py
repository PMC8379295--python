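"""Kalman machinery vs brute-force Gaussian oracles."""

import numpy as np
import pytest
from scipy import stats

import cyclessm as c
from cyclessm.datamodel import ConfigurationError
from cyclessm.statespace import impulse_matrix

from conftest import ALL_SPECS, random_instance


@pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
def test_kalman_matches_dense_oracle(spec):
    """Filtered likelihood equals the explicit joint-normal likelihood."""
    rng = np.random.default_rng(hash(spec.label) % 2**31)
    for _ in range(17):
        series, params, lam, w = random_instance(rng, spec)
        lk = c.kalman_loglik(series, spec, params, lam, w)
        lo = c.dense_loglik(series, spec, params, lam, w)
        assert lk == pytest.approx(lo, abs=1e-8)


def test_single_cycle_closed_form():
    spec = c.ModelSpec("random_walk", "none", True, ("s",))
    params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0,
                            pi=0.3, sigma_w=4.0, alpha=(0.2,))
    series = c.CycleSeries("a", [c.CycleRecord("a", 1, 29, 30.0, (3,))])
    lam, w = np.array([1.0]), np.array([2.5])
    ll = c.kalman_loglik(series, spec, params, lam, w)
    mean = 27.0 + 0.2 * 3 + 2.5
    expected = stats.norm.logpdf(29, mean, np.sqrt(1.0 ** 2 + 1.5 ** 2))
    assert ll == pytest.approx(expected, abs=1e-10)


def test_sigma_w_inactive_when_no_cycle_flagged():
    spec = c.ModelSpec("random_walk", "ma1", True, ())
    series = c.CycleSeries("a", [
        c.CycleRecord("a", j + 1, L, 30 + 0.08 * j, ())
        for j, L in enumerate([27, 29, 26, 28])])
    base = dict(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0, theta=-0.1, pi=0.3)
    lam = np.zeros(4)
    w = np.zeros(4)
    ll1 = c.kalman_loglik(series, spec, c.ParameterSet(sigma_w=4.0, **base), lam, w)
    ll2 = c.kalman_loglik(series, spec, c.ParameterSet(sigma_w=9.0, **base), lam, w)
    assert ll1 == ll2


def test_arma_with_zero_coefficients_equals_white_noise_spec():
    series = c.CycleSeries("a", [
        c.CycleRecord("a", j + 1, L, 30 + 0.08 * j, ())
        for j, L in enumerate([27, 29, 26, 28, 31])])
    p_arma = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0,
                            phi=0.0, theta=0.0)
    p_none = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0)
    ll_arma = c.kalman_loglik(series, c.ModelSpec("random_walk", "arma11", False, ()), p_arma)
    ll_none = c.kalman_loglik(series, c.ModelSpec("random_walk", "none", False, ()), p_none)
    assert ll_arma == pytest.approx(ll_none, abs=1e-10)


def test_likelihood_invariant_to_woman_ordering(small_sim):
    cohort, truth = small_sim
    spec, params = truth.spec, truth.params

    def total(series_list):
        out = 0.0
        for i, s in series_list:
            J = s.n_cycles
            out += c.kalman_loglik(s, spec, params, truth.lam[i, :J], truth.w[i, :J])
        return out

    pairs = list(enumerate(cohort.series))[:10]
    fwd = total(pairs)
    rev = total(pairs[::-1])
    assert fwd == pytest.approx(rev, rel=1e-12)


def _dense_predictive(series, spec, params, lam, w, horizon):
    """Oracle: condition the explicit (J+h)-cycle joint normal on the data."""
    J = series.n_cycles
    n = J + horizon
    mean = np.full(n, params.beta0)
    counts = np.array([r.counts for r in series.records], float)
    if spec.covariates:
        mean[:J] += counts @ np.asarray(params.alpha)
    if spec.overdispersion:
        mean[:J] += np.asarray(lam) * np.asarray(w)
    jj = np.arange(1, n + 1)
    cov = params.sigma_eta ** 2 * np.minimum.outer(jj, jj)
    if spec.error == "none":
        cov += params.sigma_eps ** 2 * np.eye(n)
    else:
        Psi = impulse_matrix(spec.error, params.phi, params.theta, n)
        cov += params.sigma_eps ** 2 * (Psi @ Psi.T)
    S11 = cov[:J, :J]
    S21 = cov[J:, :J]
    y = series.lengths
    m = mean[J:] + S21 @ np.linalg.solve(S11, y - mean[:J])
    v = np.diag(cov[J:, J:] - S21 @ np.linalg.solve(S11, S21.T))
    return m, v


@pytest.mark.parametrize("error", ["none", "ar1", "ma1", "arma11"])
def test_predictive_moments_match_conditioning_oracle(error):
    spec = c.ModelSpec("random_walk", error, True, ("s1", "s2"))
    rng = np.random.default_rng(42)
    for _ in range(5):
        series, params, lam, w = random_instance(rng, spec, j_max=8)
        means, variances = c.kalman_predict(series, spec, params, lam, w, horizon=3)
        om, ov = _dense_predictive(series, spec, params, lam, w, 3)
        np.testing.assert_allclose(means, om, atol=1e-8)
        np.testing.assert_allclose(variances, ov, atol=1e-8)


def test_predictive_degenerate_limit():
    spec = c.ModelSpec("random_walk", "none", False, ())
    params = c.ParameterSet(beta0=27.0, sigma_eps=1e-6, sigma_eta=1e-6)
    series = c.CycleSeries("a", [c.CycleRecord("a", 1, 27, 30.0, ())])
    means, variances = c.kalman_predict(series, spec, params, horizon=1)
    assert means[0] == pytest.approx(27.0, abs=1e-3)
    assert variances[0] < 1e-10


def test_random_walk_uncertainty_grows_with_horizon():
    spec = c.ModelSpec("random_walk", "ma1", False, ())
    params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0, theta=-0.1)
    series = c.CycleSeries("a", [
        c.CycleRecord("a", j + 1, L, 30 + 0.08 * j, ())
        for j, L in enumerate([27, 29, 26])])
    _, variances = c.kalman_predict(series, spec, params, horizon=4)
    assert np.all(np.diff(variances) > 0)


def test_horizon_must_be_positive():
    spec = c.ModelSpec("random_walk", "none", False, ())
    params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0)
    series = c.CycleSeries("a", [c.CycleRecord("a", 1, 27, 30.0, ())])
    with pytest.raises(ValueError):
        c.kalman_predict(series, spec, params, horizon=0)


class TestLmmTrend:
    def _series(self, ages):
        return c.CycleSeries("a", [
            c.CycleRecord("a", j + 1, 27, age, ()) for j, age in enumerate(ages)])

    def test_arithmetic(self):
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, beta1=-0.1,
                                sigma_b0=1.0, sigma_b1=0.05)
        out = c.lmm_trend(self._series([30.0]), params)
        assert out[0] == pytest.approx(24.0)

    def test_degenerate_constant(self):
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, beta1=0.0,
                                sigma_b0=1.0, sigma_b1=0.05)
        out = c.lmm_trend(self._series([30.0, 31.0, 32.0]), params)
        assert np.allclose(out, 27.0)

    def test_random_intercept_shifts_everywhere(self):
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, beta1=-0.1,
                                sigma_b0=1.0, sigma_b1=0.05)
        ages = [30.0, 30.1, 30.2]
        a = c.lmm_trend(self._series(ages), params, b0i=0.0)
        b = c.lmm_trend(self._series(ages), params, b0i=1.0)
        assert np.allclose(b - a, 1.0)


class TestBuildStateSpace:
    def test_local_level(self):
        spec = c.ModelSpec("random_walk", "none", False, ())
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0)
        m = c.build_state_space(spec, params)
        assert m.state_names == ("m",)
        assert m.transition.shape == (1, 1) and m.transition[0, 0] == 1.0
        assert m.obs_var == pytest.approx(1.5 ** 2)
        assert m.init_mean[0] == 27.0 and m.init_cov[0, 0] == pytest.approx(1.0)

    def test_ma1_augmented_state(self):
        spec = c.ModelSpec("random_walk", "ma1", False, ())
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0, theta=-0.2)
        m = c.build_state_space(spec, params)
        assert m.state_names == ("m", "z", "theta_eps")
        assert m.obs_var == 0.0
        assert m.state_cov[1, 2] == pytest.approx(-0.2 * 1.5 ** 2)

    def test_inactive_parameter_rejected(self):
        spec = c.ModelSpec("random_walk", "none", False, ())
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0, phi=0.3)
        with pytest.raises(ConfigurationError):
            c.build_state_space(spec, params)

    def test_stationarity_enforced(self):
        spec = c.ModelSpec("random_walk", "ar1", False, ())
        params = c.ParameterSet(beta0=27.0, sigma_eps=1.5, sigma_eta=1.0, phi=1.2)
        with pytest.raises(ValueError):
            c.build_state_space(spec, params)
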