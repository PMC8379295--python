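"""Reference estimates from a large observational athlete cohort.

A published analysis of ~16,500 cycles from ~2,125 athletes using a
cycle-tracking app fitted this family of models and reported posterior
summaries and a model-comparison grid.  Those printed numbers are used here
as (i) realistic ground-truth defaults for the synthetic-cohort generator and
(ii) fixed inputs for benchmark arithmetic (accuracy identity, BIC
reductions).  The underlying individual-level data are proprietary and are
not shipped or required.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "REFERENCE_POSTERIOR",
    "REFERENCE_COVARIATE_EFFECTS",
    "REFERENCE_MODEL_GRID",
    "reference_model_grid",
]

#: Posterior means (and 95% equal-tailed credible intervals) for the selected
#: model: random-walk trend + overdispersion + MA(1) + symptom covariates.
REFERENCE_POSTERIOR = {
    "beta0": {"mean": 27.4141, "se": 0.0440, "ci": (27.3283, 27.4996)},
    "pi": {"mean": 0.2636, "se": 0.0142, "ci": (0.2368, 0.2917)},
    "theta": {"mean": -0.0915, "se": 0.3160, "ci": (-0.1563, -0.0320)},
    "sigma_eta": {"mean": 1.0417, "se": 0.0231, "ci": (0.9971, 1.0875)},
    "sigma_w": {"mean": 4.7803, "se": 0.1096, "ci": (4.5738, 5.0007)},
    "sigma_eps": {"mean": 1.5407, "se": 0.0449, "ci": (1.4504, 1.6259)},
}

#: Fixed-effect estimates for the retained symptom covariates (days per
#: report).  Order matters: it is the canonical covariate order used by the
#: synthetic generator.
REFERENCE_COVARIATE_EFFECTS = {
    "injury": {"mean": 0.2965, "ci": (0.0554, 0.4768)},
    "stomach_cramps": {"mean": 0.1682, "ci": (0.0567, 0.2835)},
    "tender_breasts": {"mean": -0.1540, "ci": (-0.2443, -0.0624)},
    "flow_heavy": {"mean": -0.0816, "ci": (-0.2492, 0.0882)},
    "flow_medium": {"mean": 0.0290, "ci": (-0.0094, 0.0675)},
    "flow_light": {"mean": -0.1320, "ci": (-0.2414, -0.0239)},
    "flow_spotting": {"mean": 0.0589, "ci": (-0.0792, 0.2012)},
    "flow_none": {"mean": 0.0093, "ci": (-0.0314, 0.0492)},
}

#: Stage 1/2 model-comparison grid: hold-out forecast metrics (RMSE, Lin's
#: CCC, Pearson r between observed and one-step-ahead predicted test values)
#: and the training BIC, for the 12 candidate trend/error structures.
#: (trend, error, overdispersion) identify the structure; n_par is the parameter
#: count entering the BIC.
REFERENCE_MODEL_GRID = [
    # trend, error, overdisp, n_par, rmse, ccc, r, bic
    ("random_walk", "none", False, 3, 1.6066, 0.7327, 0.7537, 16886.70),
    ("random_walk", "ar1", False, 4, 1.5956, 0.7251, 0.7546, 17920.96),
    ("random_walk", "ma1", False, 4, 1.6108, 0.7348, 0.7533, 17694.21),
    ("random_walk", "arma11", False, 5, 1.5808, 0.7360, 0.7603, 17695.83),
    ("random_walk", "none", True, 5, 1.6449, 0.7131, 0.7283, 7393.54),
    ("random_walk", "ar1", True, 6, 1.6332, 0.7136, 0.7323, 8413.30),
    ("random_walk", "ma1", True, 6, 1.6412, 0.7266, 0.7361, 7381.61),
    ("random_walk", "arma11", True, 7, 1.6255, 0.7203, 0.7363, 7460.37),
    ("lmm_age", "none", False, 5, 1.6274, 0.7257, 0.7457, 17042.26),
    ("lmm_age", "ar1", False, 6, 1.6640, 0.7205, 0.7374, 17413.73),
    ("lmm_age", "ma1", False, 6, 1.6810, 0.7171, 0.7326, 17305.01),
    ("lmm_age", "arma11", False, 8, 1.6832, 0.7164, 0.7320, 17314.24),
]


def reference_model_grid() -> pd.DataFrame:
    """The reference comparison grid as a DataFrame."""
    return pd.DataFrame(
        REFERENCE_MODEL_GRID,
        columns=["trend", "error", "overdispersion", "n_par", "rmse", "ccc", "r", "bic"],
    )
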