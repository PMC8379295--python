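"""Scikit-learn style estimator wrapping the Bayesian cycle-length model.

:class:`CycleLengthForecaster` exposes the fit/predict surface of the
package: ``fit`` runs the Gibbs sampler on a long-format cohort frame (or a
:class:`~cyclessm.datamodel.Cohort`), ``predict`` returns one-step-ahead
point forecasts, and the fitted posterior lives in ``chains_``.  Parameters
follow the get_params/set_params contract so the estimator composes with
``sklearn.base.clone`` and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datamodel import Cohort, read_cohort
from .diagnostics import posterior_summary
from .evaluate import holdout_split, rmse
from .forecast import forecast_cohort, predictive_distribution
from .inference import McmcConfig, PriorConfig, sample_posterior
from .statespace import ModelSpec

__all__ = ["CycleLengthForecaster"]


def _as_cohort(X) -> Cohort:
    if isinstance(X, Cohort):
        return X
    if isinstance(X, pd.DataFrame):
        import io

        buf = io.StringIO()
        X.to_csv(buf, index=False)
        buf.seek(0)
        return read_cohort(buf)
    raise TypeError("X must be a Cohort or a long-format DataFrame")


class CycleLengthForecaster(BaseEstimator):
    """Bayesian state-space forecaster of menstrual cycle length.

    Parameters mirror the model specification (trend, error structure,
    overdispersion, covariates) and the MCMC layout.  After ``fit``:

    ``chains_``
        the posterior draws (:class:`~cyclessm.inference.PosteriorChains`);
    ``summary_``
        posterior means/intervals per parameter;
    ``spec_``
        the concrete :class:`~cyclessm.statespace.ModelSpec` fitted.

    Example
    -------
    >>> est = CycleLengthForecaster(n_iter=400, burn_in=200, seed=1)
    >>> est.fit(cohort_frame)                          # doctest: +SKIP
    >>> est.predict(woman_ids=["w001"], horizon=1)     # doctest: +SKIP
    """

    def __init__(self, trend: str = "random_walk", error: str = "ma1",
                 overdispersion: bool = True, covariates: tuple = (),
                 n_chains: int = 3, n_iter: int = 1000, burn_in: int = 500,
                 thin: int = 5, kappa: float = 1e-3, seed: int = 0):
        self.trend = trend
        self.error = error
        self.overdispersion = overdispersion
        self.covariates = covariates
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.kappa = kappa
        self.seed = seed

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y=None):
        cohort = _as_cohort(X)
        self.spec_ = ModelSpec(trend=self.trend, error=self.error,
                               overdispersion=self.overdispersion,
                               covariates=tuple(self.covariates))
        prior = PriorConfig(kappa=self.kappa)
        mcmc = McmcConfig(n_chains=self.n_chains, n_iter=self.n_iter,
                          burn_in=self.burn_in, thin=self.thin, seed=self.seed)
        self.chains_ = sample_posterior(cohort, self.spec_, prior=prior,
                                        mcmc=mcmc)
        self.summary_ = posterior_summary(self.chains_)
        return self

    def _check_fitted(self):
        if not hasattr(self, "chains_"):
            raise AttributeError("estimator is not fitted; call fit first")

    def predict(self, X=None, woman_ids=None, horizon: int = 1) -> np.ndarray:
        """One point forecast (days) per requested woman.

        ``woman_ids`` defaults to every woman of the training cohort; ``X``
        is accepted for pipeline compatibility and ignored.
        """
        self._check_fitted()
        data = self.chains_.data
        if woman_ids is None:
            idx = list(range(data.n_women))
        else:
            idx = [data.index_of(w) if isinstance(w, str) else int(w)
                   for w in woman_ids]
        fcs = forecast_cohort(self.chains_, indices=idx, horizon=horizon,
                              seed=self.seed)
        return np.array([f.point for f in fcs])

    def forecast(self, woman, horizon: int = 1, levels=(0.8, 0.95, 0.99)):
        """Full :class:`~cyclessm.forecast.ForecastResult` for one woman."""
        self._check_fitted()
        return predictive_distribution(self.chains_, woman, horizon=horizon,
                                       levels=levels, seed=self.seed)

    def score(self, X, y=None) -> float:
        """Negative one-step hold-out RMSE on a cohort (higher is better)."""
        cohort = _as_cohort(X)
        split = holdout_split(cohort)
        est = CycleLengthForecaster(**self.get_params())
        est.fit(split.train)
        data = est.chains_.data
        idx = [data.index_of(w) for w in split.test]
        obs = [split.test[data.woman_ids[i]].length_days for i in idx]
        pred = est.predict(woman_ids=idx)
        return -rmse(obs, pred)
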