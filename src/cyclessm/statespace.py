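"""Linear Gaussian state-space machinery for cycle-length models.

The observation model for woman i at cycle j is

    y_ij = trend_ij + gamma_ij + c_ij + r_ij

where the trend is either a random walk (m_ij = m_{i,j-1} + eta_ij, with
m_i1 ~ N(beta0, sigma_eta^2)) or a linear mixed-effects age trend
(beta0 + b0i + (beta1 + b1i) * Age_ij); gamma is an optional AR(1)/MA(1)/
ARMA(1,1) error process driven by innovations eps_ij ~ N(0, sigma_eps^2)
with zero pre-sample values (gamma_i0 = eps_i0 = 0); c_ij = sum_k alpha_k
C_ijk is the symptom-count linear predictor; and r_ij = lambda_ij * w_ij is
a Bernoulli(pi)-gated Gaussian overdispersion shock of scale sigma_w.

Conditional on (lambda, w) the model is linear Gaussian, so the likelihood
and the one-step-ahead predictive moments follow from the Kalman recursions.
The MA part is handled by state augmentation: for an ARMA(1,1) component the
state carries (z_j, theta * eps_j) with z_j = phi z_{j-1} + theta eps_{j-1}
+ eps_j.  A brute-force dense multivariate-normal likelihood
(:func:`dense_loglik`) is provided as an independent oracle.

All filter internals are batched: parameter entries may be scalars or
(B,)-arrays, enabling thousands of (woman, posterior draw) filters in a
single vectorised pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
from scipy import stats

from .datamodel import ConfigurationError, CycleSeries

__all__ = [
    "TRENDS",
    "ERRORS",
    "ModelSpec",
    "ParameterSet",
    "validate_params",
    "StateSpaceMatrices",
    "build_state_space",
    "kalman_loglik",
    "kalman_predict",
    "dense_loglik",
    "lmm_trend",
    "impulse_coefficients",
    "impulse_matrix",
]

TRENDS = ("random_walk", "lmm_age")
ERRORS = ("none", "ar1", "ma1", "arma11")


@dataclass(frozen=True)
class ModelSpec:
    """Which components of the cycle-length model are active.

    The 12 canonical candidate structures are the cross of
    trend in {random_walk, lmm_age} x error in {none, ar1, ma1, arma11},
    with overdispersion available for the random-walk trend.
    """

    trend: str = "random_walk"
    error: str = "ma1"
    overdispersion: bool = True
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.trend not in TRENDS:
            raise ConfigurationError(f"trend must be one of {TRENDS}, got {self.trend!r}")
        if self.error not in ERRORS:
            raise ConfigurationError(f"error must be one of {ERRORS}, got {self.error!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def has_ar(self) -> bool:
        return self.error in ("ar1", "arma11")

    @property
    def has_ma(self) -> bool:
        return self.error in ("ma1", "arma11")

    @property
    def label(self) -> str:
        trend = "m" if self.trend == "random_walk" else "b0+b1*Age"
        parts = [trend]
        if self.overdispersion:
            parts.append("r")
        err = {"none": "eps", "ar1": "AR(1)", "ma1": "MA(1)", "arma11": "ARMA(1,1)"}
        parts.append(err[self.error])
        lab = "y = " + " + ".join(parts)
        if self.covariates:
            lab += " + c"
        return lab


@dataclass(frozen=True)
class ParameterSet:
    """Fixed effects and variance components (Theta).

    Units: beta0 and all sigmas in days; beta1 in days/year; alpha in days per
    symptom report; pi, phi, theta dimensionless.  Fields for inactive
    components must be ``None`` (enforced by :func:`validate_params`).
    """

    beta0: float
    sigma_eps: float
    sigma_eta: float | None = None
    beta1: float | None = None
    pi: float | None = None
    phi: float | None = None
    theta: float | None = None
    alpha: tuple[float, ...] | None = None
    sigma_w: float | None = None
    sigma_b0: float | None = None
    sigma_b1: float | None = None
    sigma_b01: float = 0.0

    def with_(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


def validate_params(spec: ModelSpec, params: ParameterSet) -> None:
    """Check that exactly the parameters required by ``spec`` are supplied."""

    def active(name, cond, positive=False):
        v = getattr(params, name)
        if cond:
            if v is None:
                raise ConfigurationError(f"{name} required for spec {spec.label!r}")
            if positive and not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        elif v is not None and (np.ndim(v) or v != 0 or name in ("alpha",)):
            raise ConfigurationError(
                f"{name} supplied but inactive for spec {spec.label!r}"
            )

    if not params.sigma_eps > 0:
        raise ValueError(f"sigma_eps must be > 0, got {params.sigma_eps}")
    active("sigma_eta", spec.trend == "random_walk", positive=True)
    active("beta1", spec.trend == "lmm_age")
    active("sigma_b0", spec.trend == "lmm_age", positive=True)
    active("sigma_b1", spec.trend == "lmm_age", positive=True)
    active("phi", spec.has_ar)
    active("theta", spec.has_ma)
    active("pi", spec.overdispersion)
    active("sigma_w", spec.overdispersion, positive=True)
    if spec.has_ar and not abs(params.phi) < 1:
        raise ValueError(f"|phi| must be < 1 for a stationary AR term, got {params.phi}")
    if spec.overdispersion and not 0 <= params.pi <= 1:
        raise ValueError(f"pi must be in [0, 1], got {params.pi}")
    if spec.covariates:
        if params.alpha is None or len(params.alpha) != len(spec.covariates):
            raise ConfigurationError(
                f"alpha must have {len(spec.covariates)} entries for spec {spec.label!r}"
            )
    elif params.alpha:
        raise ConfigurationError("alpha supplied but spec has no covariates")


# ---------------------------------------------------------------------------
# ARMA impulse responses (zero pre-sample convention)
# ---------------------------------------------------------------------------

def impulse_coefficients(error: str, phi: float, theta: float, n: int) -> np.ndarray:
    """psi_0..psi_{n-1} such that gamma_j = sum_{h>=0} psi_h eps_{j-h}."""
    psi = np.zeros(n)
    if n == 0:
        return psi
    psi[0] = 1.0
    if error == "none":
        pass
    elif error == "ar1":
        psi[1:] = phi ** np.arange(1, n)
    elif error == "ma1":
        if n > 1:
            psi[1] = theta
    elif error == "arma11":
        if n > 1:
            psi[1:] = (phi + theta) * phi ** np.arange(0, n - 1)
    else:  # pragma: no cover
        raise ConfigurationError(error)
    return psi


def impulse_matrix(error: str, phi: float, theta: float, n: int) -> np.ndarray:
    """Lower-triangular Toeplitz Psi with gamma = Psi @ eps."""
    psi = impulse_coefficients(error, phi or 0.0, theta or 0.0, n)
    out = np.zeros((n, n))
    for h in range(n):
        out += np.diag(np.full(n - h, psi[h]), -h)
    return out


# ---------------------------------------------------------------------------
# batched system matrices
# ---------------------------------------------------------------------------

def _as_batch(x, B):
    a = np.asarray(0.0 if x is None else x, dtype=float)
    return np.broadcast_to(a, (B,)).astype(float, copy=False)


def _build_system(spec: ModelSpec, B: int, *, beta0, sigma_eta, sigma_eps,
                  phi, theta, sigma_b0, sigma_b1, sigma_b01, ages=None):
    """Assemble batched (T, RQR, Z, H, a1, P1) for one spec.

    Every scalar parameter may be a scalar or a (B,) array.  ``ages`` is
    required (B, J) for the lmm_age trend, whose random effects (b0, b1) are
    carried as constant states so the filter marginalises them exactly.
    Returns Z of shape (B, d) or, for lmm_age, (B, J, d).
    """
    beta0 = _as_batch(beta0, B)
    se2 = _as_batch(sigma_eps, B) ** 2
    phi_b = _as_batch(phi, B)
    th_b = _as_batch(theta, B)

    rw = spec.trend == "random_walk"
    d_trend = 1 if rw else 2
    d_err = {"none": 0, "ar1": 1, "ma1": 2, "arma11": 2}[spec.error]
    d = d_trend + d_err

    T = np.zeros((B, d, d))
    RQR = np.zeros((B, d, d))
    a1 = np.zeros((B, d))
    P1 = np.zeros((B, d, d))

    if rw:
        sh2 = _as_batch(sigma_eta, B) ** 2
        T[:, 0, 0] = 1.0
        RQR[:, 0, 0] = sh2
        a1[:, 0] = beta0
        P1[:, 0, 0] = sh2
    else:
        sb0 = _as_batch(sigma_b0, B)
        sb1 = _as_batch(sigma_b1, B)
        sb01 = _as_batch(sigma_b01, B)
        T[:, 0, 0] = 1.0
        T[:, 1, 1] = 1.0
        P1[:, 0, 0] = sb0 ** 2
        P1[:, 1, 1] = sb1 ** 2
        P1[:, 0, 1] = P1[:, 1, 0] = sb01

    i = d_trend
    if spec.error == "ar1":
        T[:, i, i] = phi_b
        RQR[:, i, i] = se2
        P1[:, i, i] = se2
    elif d_err == 2:
        # Harvey augmentation: state (z_j, theta*eps_j)
        T[:, i, i] = phi_b
        T[:, i, i + 1] = 1.0
        blk = np.empty((B, 2, 2))
        blk[:, 0, 0] = se2
        blk[:, 0, 1] = blk[:, 1, 0] = th_b * se2
        blk[:, 1, 1] = th_b ** 2 * se2
        RQR[:, i:, i:] = blk
        P1[:, i:, i:] = blk

    H = se2 if spec.error == "none" else np.zeros(B)

    if rw:
        Z = np.zeros((B, d))
        Z[:, 0] = 1.0
        if d_err:
            Z[:, d_trend] = 1.0
    else:
        if ages is None:
            raise ConfigurationError("ages required for the lmm_age trend")
        J = ages.shape[1]
        Z = np.zeros((B, J, d))
        Z[:, :, 0] = 1.0
        Z[:, :, 1] = ages
        if d_err:
            Z[:, :, d_trend] = 1.0
    return T, RQR, Z, H, a1, P1


@dataclass
class StateSpaceMatrices:
    """Concrete system matrices for one woman (convenience view).

    ``transition`` (d, d), ``state_cov`` (d, d), ``obs_vector`` (d,) or
    (J, d) when time-varying, ``obs_var`` scalar, ``init_mean`` (d,),
    ``init_cov`` (d, d).  The per-cycle observation offset (covariate term
    plus overdispersion shock, plus the fixed lmm trend) is supplied at
    filter time, never stored in the state.
    """

    transition: np.ndarray
    state_cov: np.ndarray
    obs_vector: np.ndarray
    obs_var: float
    init_mean: np.ndarray
    init_cov: np.ndarray
    state_names: tuple[str, ...] = field(default_factory=tuple)


def build_state_space(spec: ModelSpec, params: ParameterSet,
                      ages: np.ndarray | None = None) -> StateSpaceMatrices:
    """System matrices implied by ``spec``/``params`` for a single woman."""
    validate_params(spec, params)
    ages_b = None if ages is None else np.asarray(ages, float)[None, :]
    T, RQR, Z, H, a1, P1 = _build_system(
        spec, 1, beta0=params.beta0, sigma_eta=params.sigma_eta,
        sigma_eps=params.sigma_eps, phi=params.phi, theta=params.theta,
        sigma_b0=params.sigma_b0, sigma_b1=params.sigma_b1,
        sigma_b01=params.sigma_b01, ages=ages_b,
    )
    names: list[str] = ["m"] if spec.trend == "random_walk" else ["b0", "b1"]
    if spec.error == "ar1":
        names.append("gamma")
    elif spec.error in ("ma1", "arma11"):
        names += ["z", "theta_eps"]
    return StateSpaceMatrices(T[0], RQR[0], Z[0], float(np.asarray(H).ravel()[0]),
                              a1[0], P1[0], tuple(names))


# ---------------------------------------------------------------------------
# batched Kalman filter
# ---------------------------------------------------------------------------

def _run_filter(y, offset, mask, T, RQR, Z, H, a1, P1):
    """Kalman filter over contiguous observations, batched over axis 0.

    Returns (loglik, a_filt, P_filt) where the filtered moments are those at
    each batch element's last observed cycle.
    """
    B, J = y.shape
    tv = Z.ndim == 3
    a = a1.copy()
    P = P1.copy()
    ll = np.zeros(B)
    a_last = a1.copy()
    P_last = P1.copy()
    Tt = np.swapaxes(T, 1, 2)
    for j in range(J):
        Zj = Z[:, j, :] if tv else Z
        obs = mask[:, j]
        Za = np.einsum("bd,bd->b", Zj, a)
        PZ = np.einsum("bde,be->bd", P, Zj)
        F = np.einsum("bd,bd->b", Zj, PZ) + H
        v = y[:, j] - offset[:, j] - Za
        if np.any(F <= 0):
            raise ValueError("non-positive innovation variance in Kalman filter")
        K = PZ / F[:, None]
        a_f = a + K * v[:, None]
        P_f = P - K[:, :, None] * PZ[:, None, :]
        a = np.where(obs[:, None], a_f, a)
        P = np.where(obs[:, None, None], P_f, P)
        ll += np.where(obs, -0.5 * (np.log(2.0 * np.pi * F) + v * v / F), 0.0)
        a_last = np.where(obs[:, None], a, a_last)
        P_last = np.where(obs[:, None, None], P, P_last)
        if j < J - 1:
            a = np.einsum("bde,be->bd", T, a)
            P = T @ P @ Tt + RQR
            P = 0.5 * (P + np.swapaxes(P, 1, 2))
    return ll, a_last, P_last


def _predict_from_state(a, P, T, RQR, Z, H, horizon, offset_future=None,
                        Z_future=None):
    """k-step-ahead predictive means/variances from filtered moments.

    ``Z_future`` (B, k, d) overrides the observation vector per step (needed
    for the age trend); ``offset_future`` (B, k) is the known part of future
    observations (covariate forecast + fixed trend), default zero.
    """
    B, d = a.shape
    means = np.zeros((B, horizon))
    variances = np.zeros((B, horizon))
    Tt = np.swapaxes(T, 1, 2)
    for k in range(horizon):
        a = np.einsum("bde,be->bd", T, a)
        P = T @ P @ Tt + RQR
        Zk = Z_future[:, k, :] if Z_future is not None else Z
        means[:, k] = np.einsum("bd,bd->b", Zk, a)
        variances[:, k] = np.einsum("bd,bde,be->b", Zk, P, Zk) + H
        if offset_future is not None:
            means[:, k] += offset_future[:, k]
    return means, variances


# ---------------------------------------------------------------------------
# public single-series operations
# ---------------------------------------------------------------------------

def _series_offsets(series: CycleSeries, spec: ModelSpec, params: ParameterSet,
                    lam, w, counts=None):
    """Observation offset c + lambda*w (+ fixed lmm trend) for one woman."""
    J = series.n_cycles
    offset = np.zeros(J)
    if spec.covariates:
        if counts is None:
            counts = np.array([r.counts for r in series.records], dtype=float)
            if counts.shape[1] != len(spec.covariates):
                raise ConfigurationError(
                    "record covariate vectors do not match spec.covariates; "
                    "pass `counts` explicitly"
                )
        offset += counts @ np.asarray(params.alpha, dtype=float)
    if spec.overdispersion:
        lam = np.zeros(J) if lam is None else np.asarray(lam, float)
        w = np.zeros(J) if w is None else np.asarray(w, float)
        offset += lam * w
    if spec.trend == "lmm_age":
        ages = series.ages
        if not np.all(np.isfinite(ages)):
            raise ValueError("ages required for the lmm_age trend")
        offset += params.beta0 + params.beta1 * ages
    return offset


def kalman_loglik(series: CycleSeries, spec: ModelSpec, params: ParameterSet,
                  lam=None, w=None, counts=None) -> float:
    """Exact Gaussian log-likelihood (nats) of one woman's observed lengths.

    Conditional on the overdispersion indicators ``lam`` and shocks ``w`` the
    model is linear Gaussian; observed integer lengths are treated as the
    continuous process (rounding ignored).  For the lmm_age trend the random
    effects (b0i, b1i) are marginalised through the state.
    """
    validate_params(spec, params)
    y = series.lengths[None, :]
    offset = _series_offsets(series, spec, params, lam, w, counts)[None, :]
    mask = np.ones_like(y, dtype=bool)
    ages = series.ages[None, :] if spec.trend == "lmm_age" else None
    T, RQR, Z, H, a1, P1 = _build_system(
        spec, 1, beta0=params.beta0, sigma_eta=params.sigma_eta,
        sigma_eps=params.sigma_eps, phi=params.phi, theta=params.theta,
        sigma_b0=params.sigma_b0, sigma_b1=params.sigma_b1,
        sigma_b01=params.sigma_b01, ages=ages,
    )
    if spec.trend == "lmm_age":
        # the fixed part of the trend lives in the offset; state holds b only
        pass
    ll, _, _ = _run_filter(y, offset, mask, T, RQR, Z, H,
                           a1 if spec.trend == "random_walk" else np.zeros_like(a1),
                           P1)
    return float(ll[0])


def kalman_predict(series: CycleSeries, spec: ModelSpec, params: ParameterSet,
                   lam=None, w=None, horizon: int = 1, counts=None,
                   future_covariates: str = "zero",
                   age_increment: float | None = None):
    """Gaussian predictive mean/variance for the next ``horizon`` cycles.

    The future covariate offset defaults to zero (symptoms of a future cycle
    are unreported at forecast time); ``future_covariates="carry"`` repeats
    the last observed cycle's covariate offset instead.  Overdispersion of
    future cycles is *not* included here — these are the moments conditional
    on the future cycles being standard; the forecasting layer mixes over
    future lambda.

    Returns (means, variances), each of shape (horizon,).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    validate_params(spec, params)
    y = series.lengths[None, :]
    offset = _series_offsets(series, spec, params, lam, w, counts)[None, :]
    mask = np.ones_like(y, dtype=bool)
    ages = series.ages[None, :] if spec.trend == "lmm_age" else None
    T, RQR, Z, H, a1, P1 = _build_system(
        spec, 1, beta0=params.beta0, sigma_eta=params.sigma_eta,
        sigma_eps=params.sigma_eps, phi=params.phi, theta=params.theta,
        sigma_b0=params.sigma_b0, sigma_b1=params.sigma_b1,
        sigma_b01=params.sigma_b01, ages=ages,
    )
    if spec.trend == "lmm_age":
        a1 = np.zeros_like(a1)
    _, a_f, P_f = _run_filter(y, offset, mask, T, RQR, Z, H, a1, P1)

    off_fut = np.zeros((1, horizon))
    if future_covariates == "carry" and spec.covariates:
        c_last = _series_offsets(series, spec, params, None, None, counts)[-1]
        if spec.trend == "lmm_age":
            c_last -= params.beta0 + params.beta1 * series.ages[-1]
        off_fut += c_last
    elif future_covariates not in ("zero", "carry"):
        raise ConfigurationError(f"future_covariates={future_covariates!r}")

    Z_future = None
    if spec.trend == "lmm_age":
        inc = age_increment
        if inc is None:
            inc = float(series.lengths[-1]) / 365.25
        fut_ages = series.ages[-1] + inc * np.arange(1, horizon + 1)
        off_fut += params.beta0 + params.beta1 * fut_ages
        d = a_f.shape[1]
        Z_future = np.zeros((1, horizon, d))
        Z_future[:, :, 0] = 1.0
        Z_future[:, :, 1] = fut_ages
        if spec.error != "none":
            Z_future[:, :, 2] = 1.0
        Z_arg = Z[:, 0, :]  # overridden per step by Z_future
    else:
        Z_arg = Z
    means, variances = _predict_from_state(
        a_f, P_f, T, RQR, Z_arg, H, horizon,
        offset_future=off_fut, Z_future=Z_future)
    return means[0], variances[0]


def dense_loglik(series: CycleSeries, spec: ModelSpec, params: ParameterSet,
                 lam=None, w=None, counts=None) -> float:
    """Brute-force likelihood oracle: explicit joint normal of (y_1..y_J).

    Assembles the mean vector and dense covariance implied by the model
    (random-walk covariance sigma_eta^2 * min(j, k); ARMA covariance
    sigma_eps^2 Psi Psi' with zero pre-sample innovations; lmm random-effect
    covariance X G X') and evaluates the multivariate normal directly.
    Independent of the Kalman recursion by construction.
    """
    validate_params(spec, params)
    J = series.n_cycles
    mean = _series_offsets(series, spec, params, lam, w, counts).astype(float)
    cov = np.zeros((J, J))
    if spec.trend == "random_walk":
        mean += params.beta0
        jj = np.arange(1, J + 1)
        cov += params.sigma_eta ** 2 * np.minimum.outer(jj, jj)
    else:
        X = np.column_stack([np.ones(J), series.ages])
        G = np.array([[params.sigma_b0 ** 2, params.sigma_b01],
                      [params.sigma_b01, params.sigma_b1 ** 2]])
        cov += X @ G @ X.T
    if spec.error == "none":
        cov += params.sigma_eps ** 2 * np.eye(J)
    else:
        Psi = impulse_matrix(spec.error, params.phi, params.theta, J)
        cov += params.sigma_eps ** 2 * (Psi @ Psi.T)
    return float(stats.multivariate_normal(mean=mean, cov=cov).logpdf(series.lengths))


def lmm_trend(series: CycleSeries, params: ParameterSet,
              b0i: float = 0.0, b1i: float = 0.0) -> np.ndarray:
    """Subject-level age trend beta0 + b0i + (beta1 + b1i) * Age_ij."""
    ages = series.ages
    if not np.all(np.isfinite(ages)):
        raise ValueError("series has missing ages")
    beta1 = params.beta1 if params.beta1 is not None else 0.0
    return params.beta0 + b0i + (beta1 + b1i) * ages
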