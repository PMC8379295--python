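"""Gibbs sampling for the Bayesian cycle-length state-space models.

The sampler alternates exact conditional draws:

* the joint latent Gaussian states of each woman, drawn in the innovation
  parametrisation: conditional on the overdispersion cells (lambda, w) and
  the parameters, eps_i | y_i is multivariate normal (the trend m and ARMA
  component gamma are then determined by y = m + gamma + c + r), so one
  dense solve per woman replaces a sequential forward-filter
  backward-sampling pass and mixes identically;
* per-cell overdispersion indicators lambda_ij with the shock w_ij
  marginalised analytically (the odds involve the one or two random-walk
  increments the cell touches), then w_ij | lambda_ij = 1;
* conjugate updates for the mixture probability pi (Beta), all variance
  components (inverse gamma via Gamma priors on precisions), the level
  beta0, covariate effects alpha and the MA coefficient theta (Normals);
* a random-walk Metropolis step for the AR coefficient phi, whose
  conditional is not conjugate (proposal scale adapted during burn-in
  only).

Priors follow the vague conditionally-conjugate family: Gamma(1e-3, 1e-3)
on precisions, N(mu, sigma_beta^2) on levels with uniform hyper-bounds,
N(0, 100) on covariate effects and Uniform(0,1) on pi.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.signal import lfilter
from scipy.stats import truncnorm

from .datamodel import Cohort, ConfigurationError, PreparedData, prepare_arrays
from .statespace import ModelSpec, impulse_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "PosteriorChains",
    "sample_posterior",
    "overdispersion_probability",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorConfig:
    """Hyper-parameters of the prior distributions.

    ``kappa`` is the shared shape/rate of the Gamma priors on every
    precision (1e-3 by default: vague but proper).  The level beta0 has a
    normal prior whose mean is itself uniform on ``beta0_bounds`` (days);
    likewise beta1 on ``beta1_bounds`` (days/year).  AR/MA coefficients get
    a common N(mu_ar, sigma_ar^2) prior with mu_ar ~ N(0, mu_ar_prior_var)
    and a Gamma(kappa, kappa) precision; covariate effects are
    N(0, alpha_prior_var); pi is Uniform(0, 1).
    """

    kappa: float = 1e-3
    beta0_bounds: tuple[float, float] = (24.0, 32.0)
    beta1_bounds: tuple[float, float] = (-2.0, 2.0)
    mu_ar_prior_var: float = 100.0
    alpha_prior_var: float = 100.0

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.beta0_bounds[0] >= self.beta0_bounds[1]:
            raise ValueError("beta0_bounds must be ordered")


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout.  The default is the desk-scale preset (3 chains of
    1,000 sweeps, 500 burn-in, thinning 5); :meth:`full_scale` matches the
    reference analysis (burn-in 10,000, thinning 50, 3,000 saved draws per
    chain), which takes hours on a cohort of thousands."""

    n_chains: int = 3
    n_iter: int = 1000
    burn_in: int = 500
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=3, n_iter=1000, burn_in=500, thin=5, seed=seed)

    @classmethod
    def full_scale(cls, seed: int = 0) -> "McmcConfig":
        return cls(n_chains=3, n_iter=160_000, burn_in=10_000, thin=50, seed=seed)

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorChains:
    """MCMC draws indexed by (chain, saved iteration, parameter).

    ``params`` maps parameter names to (C, S) arrays ((C, S, K) for alpha).
    When ``lam`` / ``w`` are retained they are (C, S, I, Jmax) and enable
    per-cycle overdispersion probabilities and in-sample forecasting.
    ``mean_eps`` / ``mean_m`` are posterior means of the innovations and the
    trend, used by the residual diagnostics.
    """

    spec: ModelSpec
    prior: PriorConfig
    mcmc: McmcConfig
    params: dict[str, np.ndarray]
    data: PreparedData
    lam: np.ndarray | None = None
    w: np.ndarray | None = None
    mean_eps: np.ndarray | None = None
    mean_m: np.ndarray | None = None
    accept_rates: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_saved(self) -> int:
        return next(iter(self.params.values())).shape[1]

    @property
    def parameter_names(self) -> list[str]:
        names = []
        for k, v in self.params.items():
            if v.ndim == 3:
                names += [f"{k}[{c}]" for c in self.spec.covariates]
            else:
                names.append(k)
        return names

    def draws(self, name: str) -> np.ndarray:
        """Post burn-in draws of one (scalar) parameter, pooled over chains."""
        if name in self.params and self.params[name].ndim == 2:
            return self.params[name].reshape(-1)
        if "[" in name:
            base, lab = name[:-1].split("[")
            if base in self.params:
                k = list(self.spec.covariates).index(lab)
                return self.params[base][:, :, k].reshape(-1)
        raise KeyError(f"unknown parameter {name!r}; have {self.parameter_names}")

    def by_chain(self, name: str) -> np.ndarray:
        """Draws as a (C, S) array for chain diagnostics."""
        if name in self.params and self.params[name].ndim == 2:
            return self.params[name]
        if "[" in name:
            base, lab = name[:-1].split("[")
            k = list(self.spec.covariates).index(lab)
            return self.params[base][:, :, k]
        raise KeyError(name)


def _gamma_prec_draw(rng, shape, rate):
    """Variance draw via its Gamma-distributed precision.

    Clamped to [1e-12, 1e12]: with a vague Gamma(1e-3, 1e-3) prior and no
    data the precision draw can underflow to exactly zero.
    """
    draw = rng.gamma(shape, 1.0 / max(rate, 1e-300))
    return float(np.clip(1.0 / max(draw, 1e-300), 1e-12, 1e12))


def _truncnorm_draw(rng, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


class _RandomWalkGibbs:
    """Sampler for random-walk-trend specs (any error structure,
    optional overdispersion, optional covariates)."""

    def __init__(self, spec: ModelSpec, prior: PriorConfig, data: PreparedData):
        self.spec, self.prior, self.data = spec, prior, data
        I, J = data.y.shape
        self.I, self.J = I, J
        self.mask = data.mask
        self.fmask = data.mask.astype(float)
        self.N = int(data.mask.sum())
        self.y = np.where(data.mask, data.y, 0.0)
        # first-difference operator with identity first row:
        # (A m)_1 = m_1, (A m)_j = m_j - m_{j-1}
        A = np.eye(J)
        if J > 1:
            A -= np.diag(np.ones(J - 1), -1)
        self.A = A
        K = len(spec.covariates)
        self.K = K
        if K:
            sel = [data.covariate_names.index(c) for c in spec.covariates]
            self.C = data.counts[:, :, sel]
            AC = np.einsum("ab,ibk->iak", A, self.C)
            self.ACm = self.fmask[:, :, None] * AC
        else:
            self.C = np.zeros((I, J, 0))
            self.ACm = np.zeros((I, J, 0))
        # women grouped by series length (for the collapsed mixture update)
        lengths = data.mask.sum(axis=1)
        self._groups = {
            int(Jg): np.flatnonzero(lengths == Jg)
            for Jg in np.unique(lengths) if Jg > 0
        }
        self._minjk = {
            Jg: np.minimum.outer(np.arange(1, Jg + 1), np.arange(1, Jg + 1)).astype(float)
            for Jg in self._groups
        }

    # -- state ---------------------------------------------------------
    def init_state(self, rng) -> dict:
        y, mask = self.y, self.mask
        if self.N:
            ybar = float(y[mask].mean())
            sd = float(y[mask].std()) or 1.0
        else:
            ybar, sd = 28.0, 2.0
        p = self.prior
        st = {
            "beta0": ybar + 0.5 * rng.normal(),
            "mu_beta0": float(np.clip(ybar, *p.beta0_bounds)),
            "sigma_beta2": 1.0,
            "sigma_eta2": sd ** 2 * (0.2 + 0.4 * rng.random()),
            "sigma_eps2": sd ** 2 * (0.2 + 0.4 * rng.random()),
            "pi": 0.1 + 0.3 * rng.random(),
            "sigma_w2": (3.0 + 2.0 * rng.random()) ** 2,
            "theta": float(np.clip(0.2 * rng.normal(), -0.9, 0.9)),
            "phi": float(np.clip(0.2 * rng.normal(), -0.9, 0.9)),
            "mu_ar": 0.0,
            "sigma_ar2": 1.0,
            "alpha": np.zeros(self.K),
            "eps": np.zeros((self.I, self.J)),
            "lam": np.zeros((self.I, self.J)),
            "w": np.zeros((self.I, self.J)),
            "phi_scale": 0.1,
        }
        if not self.spec.has_ma:
            st["theta"] = 0.0
        if not self.spec.has_ar:
            st["phi"] = 0.0
        return st

    # -- helpers -------------------------------------------------------
    def _c_off(self, st):
        return self.C @ st["alpha"] if self.K else np.zeros((self.I, self.J))

    def _diff(self, x, beta0):
        """(A x) with beta0 subtracted from the first column, masked."""
        out = x @ self.A.T
        if self.J:
            out[:, 0] -= beta0
        return self.fmask * out

    # -- blocks --------------------------------------------------------
    def _draw_eps(self, rng, st):
        """Joint draw of each woman's innovation vector.

        Within a length group the posterior precision
        (A Psi)'(A Psi)/sigma_eta^2 + I/sigma_eps^2 is shared, so one
        Cholesky per group covers all its women.
        """
        spec = self.spec
        Psi = impulse_matrix(spec.error, st["phi"], st["theta"], self.J)
        M = self.A @ Psi
        c_off = self._c_off(st)
        s = st["lam"] * st["w"]
        o = self.y - c_off - s
        t = self._diff(o, st["beta0"])
        eps = np.zeros((self.I, self.J))
        for Jg, idx in self._groups.items():
            Mg = M[:Jg, :Jg]
            prec = Mg.T @ Mg / st["sigma_eta2"] + np.eye(Jg) / st["sigma_eps2"]
            L = np.linalg.cholesky(prec)
            rhs = (t[idx, :Jg] @ Mg) / st["sigma_eta2"]
            mean = cho_solve((L, True), rhs.T).T
            z = rng.standard_normal((idx.size, Jg))
            dev = solve_triangular(L, z.T, trans="T", lower=True).T
            eps[idx, :Jg] = mean + dev
        st["eps"] = eps
        st["Psi"] = Psi

    def _draw_overdispersion(self, rng, st):
        """Collapsed (lambda_j, w_j) update with every Gaussian state
        marginalised.

        Conditional on Theta and the other cells, y_i is multivariate
        normal with covariance Sigma = sigma_eta^2 min(j,k) + sigma_eps^2
        Psi Psi'; adding the cell's shock is a rank-1 perturbation
        sigma_w^2 e_j e_j', so the Bernoulli odds follow from a Woodbury /
        determinant-lemma identity on the precomputed Sigma^{-1}.
        Integrating the states out of this block removes the metastability
        a state-conditional update suffers when an outlier has been
        absorbed into the sampled trend.
        """
        sw2 = st["sigma_w2"]
        logit_pi = np.log(st["pi"]) - np.log1p(-st["pi"])
        Psi = impulse_matrix(self.spec.error, st["phi"], st["theta"], self.J)
        c_off = self._c_off(st)
        lam, w = st["lam"], st["w"]
        for Jg, idx in self._groups.items():
            PsiJ = Psi[:Jg, :Jg]
            Sig = (st["sigma_eta2"] * self._minjk[Jg]
                   + st["sigma_eps2"] * (PsiJ @ PsiJ.T))
            Sinv = np.linalg.inv(Sig)
            q = np.diag(Sinv)
            n = idx.size
            sg = lam[idx, :Jg] * w[idx, :Jg]
            resid = self.y[idx, :Jg] - st["beta0"] - c_off[idx, :Jg] - sg
            r = resid @ Sinv
            for j in range(Jg):
                r = r + np.outer(sg[:, j], Sinv[j])  # drop cell j from the mean
                rj = r[:, j]
                t = sw2 * q[j]
                log_ratio = -0.5 * np.log1p(t) + 0.5 * sw2 * rj * rj / (1.0 + t)
                logit = logit_pi + log_ratio
                p1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
                new_lam = rng.random(n) < p1
                prec = q[j] + 1.0 / sw2
                w_new = rj / prec + np.sqrt(1.0 / prec) * rng.standard_normal(n)
                sg[:, j] = np.where(new_lam, w_new, 0.0)
                lam[idx, j] = new_lam.astype(float)
                w[idx, j] = sg[:, j]
                r = r - np.outer(sg[:, j], Sinv[j])

    def sweep(self, rng, st):
        spec = self.spec
        # (a) collapsed overdispersion cells, then (b) the joint state draw
        # conditional on them (together an exact draw of (lambda, w, states))
        if spec.overdispersion:
            self._draw_overdispersion(rng, st)
        self._draw_eps(rng, st)
        gamma = st["eps"] @ st["Psi"].T
        c_off = self._c_off(st)
        u = self.y - c_off - gamma
        m = u - st["lam"] * st["w"]
        s = st["lam"] * st["w"]
        # (d) mixture probability
        if spec.overdispersion:
            n1 = float(st["lam"][self.mask].sum())
            st["pi"] = rng.beta(1.0 + n1, 1.0 + self.N - n1)
            sse_w = float((st["w"][self.mask] ** 2).sum())
            st["sigma_w2"] = _gamma_prec_draw(
                rng, self.prior.kappa + n1 / 2, self.prior.kappa + sse_w / 2)
        # (e) variances
        kap = self.prior.kappa
        eta = self._diff(m, st["beta0"])
        st["sigma_eta2"] = _gamma_prec_draw(
            rng, kap + self.N / 2, kap + float((eta ** 2).sum()) / 2)
        sse_eps = float((st["eps"][self.mask] ** 2).sum())
        st["sigma_eps2"] = _gamma_prec_draw(
            rng, kap + self.N / 2, kap + sse_eps / 2)
        # (f) level and its hyper-prior
        n_init = self.I if self.J else 0
        prec0 = n_init / st["sigma_eta2"] + 1.0 / st["sigma_beta2"]
        num = (float(m[:, 0].sum()) / st["sigma_eta2"] if n_init else 0.0)
        num += st["mu_beta0"] / st["sigma_beta2"]
        st["beta0"] = num / prec0 + np.sqrt(1.0 / prec0) * rng.standard_normal()
        st["mu_beta0"] = _truncnorm_draw(
            rng, st["beta0"], np.sqrt(st["sigma_beta2"]), *self.prior.beta0_bounds)
        st["sigma_beta2"] = _gamma_prec_draw(
            rng, kap + 0.5, kap + (st["beta0"] - st["mu_beta0"]) ** 2 / 2)
        # (g) covariate effects
        if self.K:
            v = self.y - gamma - s
            t = self._diff(v, st["beta0"])
            XtX = np.einsum("ijk,ijl->kl", self.ACm, self.ACm)
            Xty = np.einsum("ijk,ij->k", self.ACm, t)
            prec = XtX / st["sigma_eta2"] + np.eye(self.K) / self.prior.alpha_prior_var
            cov = np.linalg.inv(prec)
            mean = cov @ (Xty / st["sigma_eta2"])
            st["alpha"] = mean + np.linalg.cholesky(cov) @ rng.standard_normal(self.K)
            c_off = self._c_off(st)
        # (h) MA coefficient (conjugate given phi)
        if spec.has_ma:
            base = lfilter([1.0], [1.0, -st["phi"]], st["eps"], axis=1)
            lag = np.concatenate(
                [np.zeros((self.I, 1)), st["eps"][:, :-1]], axis=1)
            g = lfilter([1.0], [1.0, -st["phi"]], lag, axis=1)
            resid = self.y - c_off - s - base
            t = self._diff(resid, st["beta0"])
            gA = self.fmask * (g @ self.A.T)
            prec = float((gA ** 2).sum()) / st["sigma_eta2"] + 1.0 / st["sigma_ar2"]
            mean = ((float((gA * t).sum()) / st["sigma_eta2"]
                     + st["mu_ar"] / st["sigma_ar2"]) / prec)
            st["theta"] = mean + np.sqrt(1.0 / prec) * rng.standard_normal()
        # (i) AR coefficient (random-walk Metropolis)
        if spec.has_ar:
            def sse_of(phi):
                g2 = lfilter([1.0, st["theta"]], [1.0, -phi], st["eps"], axis=1)
                e = self._diff(self.y - c_off - s - g2, st["beta0"])
                return float((e ** 2).sum())

            cur = st["phi"]
            lp_cur = (-0.5 * sse_of(cur) / st["sigma_eta2"]
                      - 0.5 * (cur - st["mu_ar"]) ** 2 / st["sigma_ar2"])
            prop = cur + st["phi_scale"] * rng.standard_normal()
            accepted = False
            if abs(prop) < 1.0:
                lp_prop = (-0.5 * sse_of(prop) / st["sigma_eta2"]
                           - 0.5 * (prop - st["mu_ar"]) ** 2 / st["sigma_ar2"])
                if np.log(rng.random()) < lp_prop - lp_cur:
                    st["phi"] = prop
                    accepted = True
            st["phi_accept"] = accepted
        # (j) AR/MA hyper-prior
        if spec.has_ar or spec.has_ma:
            coefs = ([st["phi"]] if spec.has_ar else []) + (
                [st["theta"]] if spec.has_ma else [])
            k = len(coefs)
            prec = k / st["sigma_ar2"] + 1.0 / self.prior.mu_ar_prior_var
            mean = (sum(coefs) / st["sigma_ar2"]) / prec
            st["mu_ar"] = mean + np.sqrt(1.0 / prec) * rng.standard_normal()
            sse = sum((cc - st["mu_ar"]) ** 2 for cc in coefs)
            st["sigma_ar2"] = _gamma_prec_draw(rng, kap + k / 2, kap + sse / 2)
        # (k) state-marginalised Metropolis refresh of the variance/ARMA
        # block (the conjugate draws above are valid but diffuse slowly when
        # conditioned on the states; the marginal moves break that coupling).
        # States are re-drawn at the start of the next sweep, keeping the
        # partially collapsed scheme exact.
        if self.N:
            self._marginal_mh(rng, st)
        st["m"] = m

    def _marginal_loglik(self, st):
        """Gaussian loglik of y | beta0, alpha, lambda, w with the trend and
        ARMA states integrated out (dense per-length-group covariance)."""
        Psi = impulse_matrix(self.spec.error, st["phi"], st["theta"], self.J)
        c_off = self._c_off(st)
        s = st["lam"] * st["w"]
        ll = 0.0
        for Jg, idx in self._groups.items():
            PsiJ = Psi[:Jg, :Jg]
            Sig = (st["sigma_eta2"] * self._minjk[Jg]
                   + st["sigma_eps2"] * (PsiJ @ PsiJ.T))
            L = np.linalg.cholesky(Sig)
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
            resid = (self.y[idx, :Jg] - st["beta0"] - c_off[idx, :Jg]
                     - s[idx, :Jg])
            x = solve_triangular(L, resid.T, lower=True)
            ll += (-0.5 * (Jg * _LOG2PI + logdet) * idx.size
                   - 0.5 * float((x * x).sum()))
        return ll

    def _marginal_mh(self, rng, st):
        """One Metropolis pass over (log sigma_eta^2, log sigma_eps^2,
        theta, phi) against the Kalman marginal likelihood given
        (beta0, alpha, lambda, w)."""
        kap = self.prior.kappa

        def log_var_prior(x):  # Gamma(kappa, kappa) on the precision e^{-x}
            return -kap * x - kap * np.exp(-x)

        moves = [("sigma_eta2", "log", None), ("sigma_eps2", "log", None)]
        if self.spec.has_ma:
            moves.append(("theta", "lin", None))
        if self.spec.has_ar:
            moves.append(("phi", "lin", (-1.0, 1.0)))
        ll = self._marginal_loglik(st)
        for name, kind, bounds in moves:
            scale = st.setdefault(f"mh_{name}_scale", 0.2)
            cur = st[name]
            if kind == "log":
                x_cur = np.log(cur)
                x_prop = x_cur + scale * rng.standard_normal()
                prop = float(np.exp(x_prop))
                lp_cur = log_var_prior(x_cur)
                lp_prop = log_var_prior(x_prop)
            else:
                prop = cur + scale * rng.standard_normal()
                if bounds and not (bounds[0] < prop < bounds[1]):
                    st[f"mh_{name}_accept"] = False
                    continue
                v = st["sigma_ar2"]
                lp_cur = -0.5 * (cur - st["mu_ar"]) ** 2 / v
                lp_prop = -0.5 * (prop - st["mu_ar"]) ** 2 / v
            st[name] = prop
            ll_prop = self._marginal_loglik(st)
            if np.log(rng.random()) < (ll_prop + lp_prop) - (ll + lp_cur):
                ll = ll_prop
                st[f"mh_{name}_accept"] = True
            else:
                st[name] = cur
                st[f"mh_{name}_accept"] = False

    PARAM_NAMES = ("beta0", "pi", "theta", "phi", "sigma_eta", "sigma_w",
                   "sigma_eps")

    def snapshot(self, st) -> dict:
        out = {
            "beta0": st["beta0"],
            "sigma_eta": np.sqrt(st["sigma_eta2"]),
            "sigma_eps": np.sqrt(st["sigma_eps2"]),
        }
        if self.spec.overdispersion:
            out["pi"] = st["pi"]
            out["sigma_w"] = np.sqrt(st["sigma_w2"])
        if self.spec.has_ma:
            out["theta"] = st["theta"]
        if self.spec.has_ar:
            out["phi"] = st["phi"]
        if self.K:
            out["alpha"] = st["alpha"].copy()
        return out


class _LmmGibbs:
    """Sampler for lmm_age-trend specs (random intercept and slope in age,
    any error structure; overdispersion supported for error='none').

    The random effects are assumed independent (diagonal G); the ARMA
    coefficients use random-walk Metropolis since, with the trend
    deterministic given (beta, b), the innovations are a nonlinear filter
    of the residuals.
    """

    def __init__(self, spec: ModelSpec, prior: PriorConfig, data: PreparedData):
        if spec.overdispersion and spec.error != "none":
            raise NotImplementedError(
                "overdispersion with the lmm_age trend is only supported for "
                "error='none'")
        self.spec, self.prior, self.data = spec, prior, data
        self.I, self.J = data.y.shape
        self.mask = data.mask
        self.fmask = data.mask.astype(float)
        self.N = int(data.mask.sum())
        self.y = np.where(data.mask, data.y, 0.0)
        self.ages = np.where(data.mask, data.ages, 0.0)
        K = len(spec.covariates)
        self.K = K
        if K:
            sel = [data.covariate_names.index(c) for c in spec.covariates]
            self.C = data.counts[:, :, sel]
        else:
            self.C = np.zeros((self.I, self.J, 0))

    def init_state(self, rng) -> dict:
        if self.N:
            ybar = float(self.y[self.mask].mean())
            sd = float(self.y[self.mask].std()) or 1.0
        else:
            ybar, sd = 28.0, 2.0
        st = {
            "beta0": ybar + 0.5 * rng.normal(),
            "beta1": 0.05 * rng.normal(),
            "mu_beta0": float(np.clip(ybar, *self.prior.beta0_bounds)),
            "mu_beta1": 0.0,
            "sigma_beta2": 1.0,
            "sigma_b0_2": sd ** 2 * (0.3 + 0.4 * rng.random()),
            "sigma_b1_2": 0.01 * (0.5 + rng.random()),
            "sigma_eps2": sd ** 2 * (0.3 + 0.4 * rng.random()),
            "pi": 0.1 + 0.3 * rng.random(),
            "sigma_w2": (3.0 + 2.0 * rng.random()) ** 2,
            "theta": float(np.clip(0.2 * rng.normal(), -0.9, 0.9)),
            "phi": float(np.clip(0.2 * rng.normal(), -0.9, 0.9)),
            "mu_ar": 0.0,
            "sigma_ar2": 1.0,
            "alpha": np.zeros(self.K),
            "b": np.zeros((self.I, 2)),
            "lam": np.zeros((self.I, self.J)),
            "w": np.zeros((self.I, self.J)),
            "theta_scale": 0.1,
            "phi_scale": 0.1,
        }
        if not self.spec.has_ma:
            st["theta"] = 0.0
        if not self.spec.has_ar:
            st["phi"] = 0.0
        return st

    def _whiten(self, x, st):
        """Apply Psi^{-1} along cycles: eps_j = x_j - phi x_{j-1} - theta eps_{j-1}."""
        if self.spec.error == "none":
            return x
        return lfilter([1.0, -st["phi"]], [1.0, st["theta"]], x, axis=1)

    def _c_off(self, st):
        return self.C @ st["alpha"] if self.K else np.zeros((self.I, self.J))

    def _trend(self, st):
        return (st["beta0"] + st["b"][:, [0]]
                + (st["beta1"] + st["b"][:, [1]]) * self.ages)

    def sweep(self, rng, st):
        spec, kap = self.spec, self.prior.kappa
        c_off = self._c_off(st)
        s = st["lam"] * st["w"]
        W0 = self.fmask * self._whiten(np.ones((self.I, self.J)) * self.fmask, st)
        W1 = self.fmask * self._whiten(self.ages, st)
        se2 = st["sigma_eps2"]

        # (a) random effects b_i
        r0 = self.y - (st["beta0"] + st["beta1"] * self.ages) - c_off - s
        d = self.fmask * self._whiten(r0, st)
        s00 = (W0 * W0).sum(axis=1) / se2 + 1.0 / st["sigma_b0_2"]
        s11 = (W1 * W1).sum(axis=1) / se2 + 1.0 / st["sigma_b1_2"]
        s01 = (W0 * W1).sum(axis=1) / se2
        r_0 = (W0 * d).sum(axis=1) / se2
        r_1 = (W1 * d).sum(axis=1) / se2
        det = s00 * s11 - s01 * s01
        mb0 = (s11 * r_0 - s01 * r_1) / det
        mb1 = (s00 * r_1 - s01 * r_0) / det
        # Cholesky of the 2x2 covariance (inverse of the precision)
        c00 = s11 / det
        c01 = -s01 / det
        c11 = s00 / det
        l00 = np.sqrt(c00)
        l10 = c01 / l00
        l11 = np.sqrt(np.maximum(c11 - l10 ** 2, 1e-300))
        z = rng.standard_normal((self.I, 2))
        st["b"] = np.column_stack([mb0 + l00 * z[:, 0],
                                   mb1 + l10 * z[:, 0] + l11 * z[:, 1]])

        # (b) fixed effects (beta0, beta1)
        rB = self.y - (st["b"][:, [0]] + st["b"][:, [1]] * self.ages) - c_off - s
        t = self.fmask * self._whiten(rB, st)
        sb2 = st["sigma_beta2"]
        P00 = (W0 * W0).sum() / se2 + 1.0 / sb2
        P11 = (W1 * W1).sum() / se2 + 1.0 / sb2
        P01 = (W0 * W1).sum() / se2
        q0 = (W0 * t).sum() / se2 + st["mu_beta0"] / sb2
        q1 = (W1 * t).sum() / se2 + st["mu_beta1"] / sb2
        detP = P00 * P11 - P01 * P01
        mean = np.array([(P11 * q0 - P01 * q1) / detP,
                         (P00 * q1 - P01 * q0) / detP])
        cov = np.array([[P11, -P01], [-P01, P00]]) / detP
        st["beta0"], st["beta1"] = rng.multivariate_normal(mean, cov)
        st["mu_beta0"] = _truncnorm_draw(
            rng, st["beta0"], np.sqrt(sb2), *self.prior.beta0_bounds)
        st["mu_beta1"] = _truncnorm_draw(
            rng, st["beta1"], np.sqrt(sb2), *self.prior.beta1_bounds)
        st["sigma_beta2"] = _gamma_prec_draw(
            rng, kap + 1.0,
            kap + ((st["beta0"] - st["mu_beta0"]) ** 2
                   + (st["beta1"] - st["mu_beta1"]) ** 2) / 2)

        # (c) covariate effects
        trend = self._trend(st)
        if self.K:
            rA = self.y - trend - s
            tA = self.fmask * self._whiten(rA, st)
            WC = self._whiten(self.C, st) * self.fmask[:, :, None]
            XtX = np.einsum("ijk,ijl->kl", WC, WC)
            Xty = np.einsum("ijk,ij->k", WC, tA)
            prec = XtX / se2 + np.eye(self.K) / self.prior.alpha_prior_var
            cov = np.linalg.inv(prec)
            meanA = cov @ (Xty / se2)
            st["alpha"] = meanA + np.linalg.cholesky(cov) @ rng.standard_normal(self.K)
            c_off = self._c_off(st)

        # (d) overdispersion cells (error='none' only): resid = eps + lam*w
        if spec.overdispersion:
            resid = self.y - trend - c_off
            sw = st["sigma_w2"]
            logit = (np.log(st["pi"]) - np.log1p(-st["pi"])
                     - 0.5 * np.log((se2 + sw) / se2)
                     - resid ** 2 / 2 * (1 / (se2 + sw) - 1 / se2))
            p1 = 1.0 / (1.0 + np.exp(-np.clip(logit, -700, 700)))
            new_lam = (rng.random((self.I, self.J)) < p1) & self.mask
            prec_w = 1.0 / sw + 1.0 / se2
            mean_w = resid / se2 / prec_w
            draw = mean_w + np.sqrt(1.0 / prec_w) * rng.standard_normal(
                (self.I, self.J))
            st["lam"] = new_lam.astype(float)
            st["w"] = np.where(new_lam, draw, 0.0)
            s = st["lam"] * st["w"]
            n1 = float(st["lam"][self.mask].sum())
            st["pi"] = rng.beta(1.0 + n1, 1.0 + self.N - n1)
            st["sigma_w2"] = _gamma_prec_draw(
                rng, kap + n1 / 2,
                kap + float((st["w"][self.mask] ** 2).sum()) / 2)

        # (e) random-effect variances
        st["sigma_b0_2"] = _gamma_prec_draw(
            rng, kap + self.I / 2, kap + float((st["b"][:, 0] ** 2).sum()) / 2)
        st["sigma_b1_2"] = _gamma_prec_draw(
            rng, kap + self.I / 2, kap + float((st["b"][:, 1] ** 2).sum()) / 2)

        # (f) innovation variance
        resid_full = self.y - trend - c_off - s
        eps = self.fmask * self._whiten(resid_full, st)
        st["eps"] = eps
        st["sigma_eps2"] = _gamma_prec_draw(
            rng, kap + self.N / 2, kap + float((eps[self.mask] ** 2).sum()) / 2)

        # (g) ARMA coefficients by Metropolis
        for nm, active in (("theta", spec.has_ma), ("phi", spec.has_ar)):
            if not active:
                continue

            def lp(val):
                trial = dict(st)
                trial[nm] = val
                e = self.fmask * self._whiten(resid_full, trial)
                return (-0.5 * float((e ** 2).sum()) / st["sigma_eps2"]
                        - 0.5 * (val - st["mu_ar"]) ** 2 / st["sigma_ar2"])

            cur = st[nm]
            prop = cur + st[f"{nm}_scale"] * rng.standard_normal()
            ok = abs(prop) < 1.0
            if ok and np.log(rng.random()) < lp(prop) - lp(cur):
                st[nm] = prop
                st[f"{nm}_accept"] = True
            else:
                st[f"{nm}_accept"] = False
        if spec.has_ar or spec.has_ma:
            coefs = ([st["phi"]] if spec.has_ar else []) + (
                [st["theta"]] if spec.has_ma else [])
            k = len(coefs)
            prec = k / st["sigma_ar2"] + 1.0 / self.prior.mu_ar_prior_var
            meanH = (sum(coefs) / st["sigma_ar2"]) / prec
            st["mu_ar"] = meanH + np.sqrt(1.0 / prec) * rng.standard_normal()
            st["sigma_ar2"] = _gamma_prec_draw(
                rng, kap + k / 2,
                kap + sum((cc - st["mu_ar"]) ** 2 for cc in coefs) / 2)
        st["m"] = trend

    def snapshot(self, st) -> dict:
        out = {
            "beta0": st["beta0"],
            "beta1": st["beta1"],
            "sigma_b0": np.sqrt(st["sigma_b0_2"]),
            "sigma_b1": np.sqrt(st["sigma_b1_2"]),
            "sigma_eps": np.sqrt(st["sigma_eps2"]),
        }
        if self.spec.overdispersion:
            out["pi"] = st["pi"]
            out["sigma_w"] = np.sqrt(st["sigma_w2"])
        if self.spec.has_ma:
            out["theta"] = st["theta"]
        if self.spec.has_ar:
            out["phi"] = st["phi"]
        if self.K:
            out["alpha"] = st["alpha"].copy()
        return out


def sample_posterior(cohort: Cohort | PreparedData, spec: ModelSpec,
                     prior: PriorConfig | None = None,
                     mcmc: McmcConfig | None = None,
                     retain_latent: bool = True,
                     progress: bool = False) -> PosteriorChains:
    """Run the Gibbs sampler and collect thinned post-burn-in draws.

    Deterministic given ``mcmc.seed``: chain c uses the c-th spawned
    substream.  An empty cohort is allowed and yields draws from the prior
    (useful for prior-predictive checks).  Women with a single cycle
    contribute only the initial-level term and are logged.
    """
    prior = prior or PriorConfig()
    mcmc = mcmc or McmcConfig()
    data = cohort if isinstance(cohort, PreparedData) else prepare_arrays(cohort)
    missing = [c for c in spec.covariates if c not in data.covariate_names]
    if missing:
        raise ConfigurationError(f"spec covariates not in cohort: {missing}")
    n_single = int((data.lengths == 1).sum())
    if n_single:
        logger.info("%d woman/women with a single cycle (initial term only)",
                    n_single)

    cls = _RandomWalkGibbs if spec.trend == "random_walk" else _LmmGibbs
    sampler = cls(spec, prior, data)

    C, S = mcmc.n_chains, mcmc.n_saved
    store: dict[str, np.ndarray] = {}
    lam_store = w_store = None
    if retain_latent and spec.overdispersion:
        lam_store = np.zeros((C, S, data.n_women, data.j_max), dtype=np.float32)
        w_store = np.zeros((C, S, data.n_women, data.j_max), dtype=np.float32)
    sum_eps = np.zeros((data.n_women, data.j_max))
    sum_m = np.zeros((data.n_women, data.j_max))
    n_acc: dict[str, int] = {}
    n_tot: dict[str, int] = {}

    seeds = np.random.SeedSequence(mcmc.seed).spawn(C)
    for c in range(C):
        rng = np.random.Generator(np.random.PCG64(seeds[c]))
        st = sampler.init_state(rng)
        k = 0
        for it in range(mcmc.n_iter):
            sampler.sweep(rng, st)
            for key in [k for k in st if k.endswith("_accept")]:
                nm = key[: -len("_accept")]
                acc = bool(st[key])
                if it < mcmc.burn_in:  # adapt proposal scales during burn-in only
                    sc = st.get(f"{nm}_scale", 0.1)
                    st[f"{nm}_scale"] = float(np.clip(
                        sc * np.exp((acc - 0.44) / np.sqrt(1 + it / 10)),
                        1e-3, 2.0))
                else:
                    n_acc[nm] = n_acc.get(nm, 0) + acc
                    n_tot[nm] = n_tot.get(nm, 0) + 1
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                snap = sampler.snapshot(st)
                for name, val in snap.items():
                    if name not in store:
                        shape = (C, S) + (np.shape(val) or ())
                        store[name] = np.zeros(shape)
                    store[name][c, k] = val
                if lam_store is not None:
                    lam_store[c, k] = st["lam"]
                    w_store[c, k] = st["w"]
                sum_eps += st.get("eps", np.zeros_like(sum_eps))
                sum_m += st.get("m", np.zeros_like(sum_m))
                k += 1
            if not np.isfinite(st["sigma_eps2"]):
                raise RuntimeError(f"sampler diverged at chain {c} iteration {it}")
        if progress:
            logger.info("chain %d/%d done", c + 1, C)

    n_draws = C * S
    accept = {nm: (n_acc[nm] / n_tot[nm]) for nm in n_acc if n_tot[nm]}
    return PosteriorChains(
        spec=spec, prior=prior, mcmc=mcmc, params=store, data=data,
        lam=lam_store, w=w_store,
        mean_eps=sum_eps / n_draws, mean_m=sum_m / n_draws,
        accept_rates=accept,
    )


def overdispersion_probability(chains: PosteriorChains, woman, cycle_index: int) -> float:
    """Posterior probability that a given cycle was overdispersed.

    ``woman`` may be a woman_id or a positional index; ``cycle_index`` is
    1-based.  Requires lambda draws to have been retained.
    """
    if chains.lam is None:
        raise ValueError(
            "lambda draws were not retained; re-run sample_posterior with "
            "retain_latent=True and an overdispersion spec")
    i = woman if isinstance(woman, (int, np.integer)) else chains.data.index_of(woman)
    j = cycle_index - 1
    if not (0 <= i < chains.data.n_women) or not chains.data.mask[i, j]:
        raise IndexError(f"no observed cycle at (woman {woman}, cycle {cycle_index})")
    return float(chains.lam[:, :, i, j].mean())
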