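"""Forward simulation of synthetic cycle-length cohorts.

The generator draws cohorts from the full generative model with known
ground-truth parameters and latent states, emulating the shape of large
cycle-tracking app cohorts: ~2,000 women contributing 4-53 cycles each,
mean length around 27.4 days, roughly a quarter of cycles overdispersed,
and sparse per-cycle symptom report counts.  Defaults for the model
parameters come from :mod:`cyclessm.reference`.

Symptom counts are simulated independently of cycle length (the generative
direction of the model is covariate -> length) as independent Poissons with
configurable rates; real app data additionally show reporting-engagement
effects that this generator does not attempt to emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .datamodel import Cohort, CycleRecord, CycleSeries
from .reference import REFERENCE_COVARIATE_EFFECTS, REFERENCE_POSTERIOR
from .statespace import ModelSpec, ParameterSet, validate_params

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "simulate_cohort",
    "round_to_days",
    "inject_outlier_cycles",
    "reference_parameters",
    "DEFAULT_COVARIATE_RATES",
]

#: Mean per-cycle report counts for the default symptom set.  Chosen so that
#: most cells are zero (symptoms mostly unreported) while flow levels are
#: logged a few times per cycle, mirroring the sparsity of app logs.
DEFAULT_COVARIATE_RATES = {
    "injury": 0.10,
    "stomach_cramps": 0.60,
    "tender_breasts": 0.50,
    "flow_heavy": 0.70,
    "flow_medium": 1.50,
    "flow_light": 1.20,
    "flow_spotting": 0.40,
    "flow_none": 0.30,
}


def reference_parameters(spec: ModelSpec) -> ParameterSet:
    """Ground-truth :class:`ParameterSet` for ``spec`` from the reference study.

    Posterior means of the selected model are used for every component the
    spec activates; covariate effects are looked up by name (unknown names
    get effect 0).
    """
    post = {k: v["mean"] for k, v in REFERENCE_POSTERIOR.items()}
    kw: dict = {"beta0": post["beta0"], "sigma_eps": post["sigma_eps"]}
    if spec.trend == "random_walk":
        kw["sigma_eta"] = post["sigma_eta"]
    else:
        kw.update(beta1=-0.05, sigma_b0=1.0, sigma_b1=0.05)
    if spec.has_ar:
        kw["phi"] = 0.2
    if spec.has_ma:
        kw["theta"] = post["theta"]
    if spec.overdispersion:
        kw.update(pi=post["pi"], sigma_w=post["sigma_w"])
    if spec.covariates:
        kw["alpha"] = tuple(
            REFERENCE_COVARIATE_EFFECTS.get(name, {"mean": 0.0})["mean"]
            for name in spec.covariates
        )
    return ParameterSet(**kw)


@dataclass
class CohortDesign:
    """Shape of a simulated cohort.

    cycles per woman ~ discrete uniform on ``cycles_range`` (inclusive);
    starting age ~ uniform on ``age_start_range`` years; age then advances by
    the realised cycle length in days / 365.25.  ``covariate_rates`` maps
    symptom names to Poisson report-count means.
    """

    n_women: int = 200
    cycles_range: tuple[int, int] = (4, 53)
    age_start_range: tuple[float, float] = (18.0, 47.0)
    covariate_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RATES)
    )

    def __post_init__(self):
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        lo, hi = self.cycles_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid cycles_range {self.cycles_range}")
        if any(r < 0 for r in self.covariate_rates.values()):
            raise ValueError("covariate rates must be >= 0")


@dataclass
class GroundTruth:
    """Latent states stored alongside a simulated cohort (padded arrays)."""

    spec: ModelSpec
    params: ParameterSet
    mask: np.ndarray          # (I, J) valid cells
    m: np.ndarray             # trend component
    gamma: np.ndarray         # full ARMA error component (zero if error none... includes eps)
    eps: np.ndarray           # innovations
    eta: np.ndarray           # random-walk increments (rw trend only)
    lam: np.ndarray           # overdispersion indicators in {0, 1}
    w: np.ndarray             # overdispersion shocks (days)
    c: np.ndarray             # covariate linear predictor
    y: np.ndarray             # continuous latent cycle length

    @property
    def r(self) -> np.ndarray:
        return self.lam * self.w

    def max_conservation_error(self) -> float:
        """max |y - (m + gamma + c + r)| over valid cells; 0 up to float error."""
        resid = self.y - (self.m + self.gamma + self.c + self.r)
        return float(np.abs(np.where(self.mask, resid, 0.0)).max())


def round_to_days(y) -> np.ndarray:
    """Nearest-integer rounding of continuous lengths; halves round away
    from zero (27.5 -> 28, -27.5 -> -28)."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("cannot round non-finite cycle length")
    out = np.sign(y) * np.floor(np.abs(y) + 0.5)
    return out.astype(int) if out.ndim else int(out)


def _woman_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # one deterministic substream per woman: woman i's draws do not change
    # when the cohort grows
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.Generator(np.random.PCG64(c)) for c in children]


def simulate_cohort(design: CohortDesign, params: ParameterSet, spec: ModelSpec,
                    seed: int) -> tuple[Cohort, GroundTruth]:
    """Draw a cohort from the generative model.  Deterministic given ``seed``.

    Every latent quantity (trend, ARMA component, innovations, overdispersion
    indicators and shocks, continuous lengths) is returned in the
    :class:`GroundTruth` so recovery tests can condition on the truth.
    Observed integer lengths are the rounded continuous lengths.
    """
    validate_params(spec, params)
    names = list(design.covariate_rates)
    missing = [c for c in spec.covariates if c not in names]
    if missing:
        raise ValueError(f"spec covariates missing from design rates: {missing}")
    rates = np.array([design.covariate_rates[n] for n in names])
    alpha_full = np.zeros(len(names))
    if spec.covariates:
        pos = {n: i for i, n in enumerate(names)}
        for k, n in enumerate(spec.covariates):
            alpha_full[pos[n]] = params.alpha[k]

    rngs = _woman_rngs(seed, design.n_women)
    lo, hi = design.cycles_range
    a_lo, a_hi = design.age_start_range
    phi = params.phi or 0.0
    theta = params.theta or 0.0

    J_all = [int(r.integers(lo, hi + 1)) for r in rngs]
    jmax = max(J_all)
    I = design.n_women
    shp = (I, jmax)
    mask = np.zeros(shp, dtype=bool)
    m_arr, g_arr, e_arr, h_arr, l_arr, w_arr, c_arr, y_arr = (
        np.zeros(shp) for _ in range(8))
    ages_arr = np.zeros(shp)
    counts_arr = np.zeros((I, jmax, len(names)))
    o_arr = np.zeros(shp, dtype=int)

    for i, (rng, J) in enumerate(zip(rngs, J_all)):
        mask[i, :J] = True
        counts = rng.poisson(rates, size=(J, len(names))).astype(float)
        c = counts @ alpha_full
        eps = rng.normal(0.0, params.sigma_eps, size=J)
        gamma = lfilter([1.0, theta], [1.0, -phi], eps)
        if spec.overdispersion:
            lam = (rng.random(J) < params.pi).astype(float)
            w = rng.normal(0.0, params.sigma_w, size=J)
        else:
            lam = np.zeros(J)
            w = np.zeros(J)
        age0 = rng.uniform(a_lo, a_hi)
        if spec.trend == "random_walk":
            eta = rng.normal(0.0, params.sigma_eta, size=J)
            m = params.beta0 + np.cumsum(eta)
            y = m + gamma + c + lam * w
            o = round_to_days(y)
            ages = age0 + np.concatenate([[0.0], np.cumsum(o[:-1]) / 365.25])
        else:
            b = rng.multivariate_normal(
                [0.0, 0.0],
                [[params.sigma_b0 ** 2, params.sigma_b01],
                 [params.sigma_b01, params.sigma_b1 ** 2]])
            eta = np.zeros(J)
            ages = np.zeros(J)
            m = np.zeros(J)
            y = np.zeros(J)
            o = np.zeros(J, dtype=int)
            age = age0
            for j in range(J):
                ages[j] = age
                m[j] = params.beta0 + b[0] + (params.beta1 + b[1]) * age
                y[j] = m[j] + gamma[j] + c[j] + lam[j] * w[j]
                o[j] = round_to_days(y[j])
                age += o[j] / 365.25
        m_arr[i, :J] = m
        g_arr[i, :J] = gamma
        e_arr[i, :J] = eps
        h_arr[i, :J] = eta
        l_arr[i, :J] = lam
        w_arr[i, :J] = w
        c_arr[i, :J] = c
        y_arr[i, :J] = y
        ages_arr[i, :J] = ages
        counts_arr[i, :J] = counts
        o_arr[i, :J] = o

    cohort = _cohort_from_arrays(o_arr, ages_arr, counts_arr, mask, names)
    truth = GroundTruth(spec, params, mask, m_arr, g_arr, e_arr, h_arr,
                        l_arr, w_arr, c_arr, y_arr)
    return cohort, truth


def _cohort_from_arrays(o, ages, counts, mask, names) -> Cohort:
    series = []
    width = len(str(o.shape[0]))
    for i in range(o.shape[0]):
        wid = f"w{i:0{width}d}"
        J = int(mask[i].sum())
        recs = [
            CycleRecord(wid, j + 1, int(o[i, j]), float(ages[i, j]),
                        tuple(int(v) for v in counts[i, j]))
            for j in range(J)
        ]
        series.append(CycleSeries(wid, recs))
    return Cohort(series=series, covariate_names=list(names))


def inject_outlier_cycles(cohort: Cohort, truth: GroundTruth,
                          indices: Sequence[tuple[int, int]], seed: int = 0,
                          min_magnitude: float | None = None):
    """Force overdispersion (lambda=1, fresh w) at the given cells.

    ``indices`` are (woman position, 1-based cycle index) pairs.  With
    ``min_magnitude`` the redrawn shock is conditioned on |w| >= that value,
    which makes the injected cells unambiguous outliers for detection tests.
    Returns a new (Cohort, GroundTruth) pair, leaving the inputs untouched.
    """
    if not truth.spec.overdispersion:
        raise ValueError("ground truth was simulated without overdispersion")
    rng = np.random.default_rng(seed)
    lam = truth.lam.copy()
    w = truth.w.copy()
    for i, j1 in indices:
        j = j1 - 1
        if not (0 <= i < truth.mask.shape[0]) or not (
                0 <= j < truth.mask.shape[1]) or not truth.mask[i, j]:
            raise IndexError(f"no observed cycle at (woman {i}, cycle {j1})")
        lam[i, j] = 1.0
        draw = rng.normal(0.0, truth.params.sigma_w)
        if min_magnitude is not None:
            while abs(draw) < min_magnitude:
                draw = rng.normal(0.0, truth.params.sigma_w)
        w[i, j] = draw
    y = truth.m + truth.gamma + truth.c + lam * w
    new_truth = GroundTruth(truth.spec, truth.params, truth.mask, truth.m,
                            truth.gamma, truth.eps, truth.eta, lam, w,
                            truth.c, y)
    o = np.where(truth.mask, round_to_days(np.where(truth.mask, y, 0.0)), 0)
    ages = np.zeros_like(y)
    counts = np.zeros((y.shape[0], y.shape[1], len(cohort.covariate_names)))
    for i, s in enumerate(cohort.series):
        J = s.n_cycles
        ages[i, :J] = s.ages
        for j, r in enumerate(s.records):
            counts[i, j] = r.counts
    new_cohort = _cohort_from_arrays(o, ages, counts, truth.mask,
                                     list(cohort.covariate_names))
    return new_cohort, new_truth
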