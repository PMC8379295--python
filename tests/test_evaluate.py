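"""Metrics, BIC, hold-out machinery, selection rules, diagnostics."""

import numpy as np
import pytest

import cyclessm as c
from cyclessm.evaluate import _N_PAR, parameter_count
from cyclessm.inference import McmcConfig, PosteriorChains, PriorConfig


class TestRmse:
    def test_identical_is_zero(self):
        assert c.rmse([27, 28], [27, 28]) == 0.0

    def test_unit_errors(self):
        assert c.rmse([1, -1], [0, 0]) == pytest.approx(1.0)

    def test_three_four(self):
        assert c.rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            c.rmse([1, 2], [1])


class TestCcc:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert c.ccc(x, x) == pytest.approx(1.0)

    def test_location_shift_closed_form(self):
        # var 1 each, shift 5: 2*1 / (1 + 1 + 25)
        rng = np.random.default_rng(0)
        x = rng.normal(size=200_000)
        x = (x - x.mean()) / x.std()
        assert c.ccc(x, x + 5) == pytest.approx(2.0 / 27.0, abs=1e-12)

    def test_identity_ccc_r_cb(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = 0.6 * x + rng.normal(size=500)
        cc = c.ccc(x, y)
        r = float(np.corrcoef(x, y)[0, 1])
        assert cc == pytest.approx(r * c.accuracy_cb(cc, r), abs=1e-12)
        assert abs(cc) <= abs(r)

    def test_equal_moments_gives_ccc_equal_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100_000)
        y = 0.5 * x + np.sqrt(0.75) * rng.normal(size=100_000)
        assert c.ccc(x, y) == pytest.approx(float(np.corrcoef(x, y)[0, 1]),
                                            abs=2e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            c.ccc([1.0, 1.0], [1.0, 2.0])


class TestAccuracyCb:
    def test_reference_row(self):
        assert round(c.accuracy_cb(0.7266, 0.7361), 4) == 0.9871

    def test_trivia(self):
        assert c.accuracy_cb(0.5, 1.0) == 0.5
        assert c.accuracy_cb(0.9, 0.9) == pytest.approx(1.0)

    def test_zero_r_rejected(self):
        with pytest.raises(ValueError):
            c.accuracy_cb(0.5, 0.0)


class TestBic:
    def test_direct_evaluation(self):
        expected = 8 * np.log(1.25) + 2 * np.log(5.0)
        assert c.bic(10, 2, 1.0, 20.0) == pytest.approx(expected, abs=1e-10)
        assert c.bic(10, 2, 1.0, 20.0) == pytest.approx(5.0040, abs=5e-4)

    def test_boundary_p_close_to_n(self):
        out = c.bic(10, 9, 1.0, 20.0)
        assert np.isfinite(out)
        assert out == pytest.approx(np.log(10.0) + 9 * np.log(10.0 / 9.0), abs=1e-10)

    def test_log_domain_errors(self):
        with pytest.raises(ValueError):
            c.bic(10, 2, 2.0, 20.0)  # sum_y_sq <= N sigma^2
        with pytest.raises(ValueError):
            c.bic(2, 2, 1.0, 20.0)

    def test_monotone_in_sigma(self):
        vals = [c.bic(100, 5, s2, 100_000.0) for s2 in np.linspace(0.5, 8, 25)]
        assert np.all(np.diff(vals) > 0)


def test_parameter_count_lookup():
    from cyclessm.reference import reference_model_grid
    grid = reference_model_grid()
    for _, row in grid.iterrows():
        spec = c.ModelSpec(row["trend"], row["error"], row["overdispersion"], ())
        assert parameter_count(spec) == row["n_par"]
    spec = c.ModelSpec("random_walk", "ma1", True, ("a", "b", "c"))
    assert parameter_count(spec) == _N_PAR[("random_walk", "ma1", True)] + 3


class TestHoldout:
    def test_last_cycle_held_back(self, small_sim):
        cohort, _ = small_sim
        split = c.holdout_split(cohort)
        assert len(split.test) == cohort.I
        for s, t in zip(cohort.series, split.train.series):
            assert t.n_cycles == s.n_cycles - 1
            assert split.test[s.woman_id].length_days == s.records[-1].length_days

    def test_single_cycle_women_train_only(self):
        series = [c.CycleSeries("a", [c.CycleRecord("a", 1, 27, 30.0, ())]),
                  c.CycleSeries("b", [c.CycleRecord("b", j + 1, 28, 25.0, ())
                                      for j in range(3)])]
        split = c.holdout_split(c.Cohort(series=series, covariate_names=[]))
        assert "a" not in split.test
        assert split.train.woman("a").n_cycles == 1
        assert split.train.woman("b").n_cycles == 2


def _synthetic_alpha_chains(draw_map):
    """Minimal chains object with given alpha draws per covariate."""
    names = tuple(draw_map)
    draws = np.stack([np.asarray(draw_map[k]) for k in names], axis=-1)[None]
    spec = c.ModelSpec("random_walk", "none", False, names)
    data = c.prepare_arrays(c.Cohort(series=[], covariate_names=list(names)))
    return PosteriorChains(spec=spec, prior=PriorConfig(), mcmc=McmcConfig(seed=0),
                           params={"alpha": draws}, data=data)


class TestSelectCovariates:
    def test_signal_retained_null_dropped(self):
        rng = np.random.default_rng(0)
        chains = _synthetic_alpha_chains({
            "strong": 0.3 + 0.05 * rng.normal(size=400),
            "null": 0.05 * rng.normal(size=400),
        })
        assert c.select_covariates(chains) == ["strong"]

    def test_all_positive_draws_retained(self):
        chains = _synthetic_alpha_chains({"s": np.linspace(0.1, 0.4, 100)})
        assert c.select_covariates(chains) == ["s"]

    def test_power_on_synthetic_fit(self):
        """With one real and one null effect, the stage-3 rule keeps the
        real one and drops the null."""
        spec = c.ModelSpec("random_walk", "none", True,
                           ("stomach_cramps", "flow_none"))
        params = c.reference_parameters(spec).with_(
            alpha=(0.25, 0.0))
        cohort, _ = c.simulate_cohort(
            c.CohortDesign(n_women=250, cycles_range=(5, 10)), params, spec,
            seed=13)
        ch = c.sample_posterior(cohort, spec,
                                mcmc=c.McmcConfig(n_iter=600, burn_in=300,
                                                  thin=5, seed=14))
        kept = c.select_covariates(ch)
        assert "stomach_cramps" in kept
        assert "flow_none" not in kept


class TestSelection:
    def test_single_spec_grid_returned(self, small_sim):
        cohort, _ = small_sim
        spec = c.ModelSpec("random_walk", "none", True, ())
        table, chosen = c.select_model(
            cohort, [spec],
            mcmc=c.McmcConfig(n_iter=200, burn_in=100, thin=5, seed=2))
        assert chosen == spec
        assert len(table) == 1

    def test_random_walk_data_beats_lmm_on_bic(self, small_sim):
        """A wandering trend inflates the LMM residual variance, so the
        random-walk family wins the information criterion."""
        cohort, _ = small_sim
        grid = [c.ModelSpec("random_walk", "none", True, ()),
                c.ModelSpec("lmm_age", "none", False, ())]
        table, chosen = c.select_model(
            cohort, grid, mcmc=c.McmcConfig(n_iter=400, burn_in=200, thin=5,
                                            seed=3))
        rw_bic = table.loc[table["model"].str.startswith("y = m"), "bic"].min()
        lmm_bic = table.loc[~table["model"].str.startswith("y = m"), "bic"].min()
        assert rw_bic < lmm_bic


class TestAttrition:
    def test_scenarios_shrink_monotonically(self, small_fit):
        cohort, chains = small_fit
        ids = [s.woman_id for s in cohort.series[::2]]
        table = c.attrition_evaluation(chains, ids, min_cycles=3, max_cycles=12)
        n = table["N"].to_numpy()
        assert np.all(np.diff(n) <= 0)
        assert table.loc[table["n_cycles"] == 3, "N"].iloc[0] == len(ids)

    def test_exhausted_pool_gives_empty_rows(self, small_fit):
        cohort, chains = small_fit
        table = c.attrition_evaluation(chains, [0, 1], min_cycles=3,
                                       max_cycles=30)
        last = table.iloc[-1]
        assert last["N"] == 0 and np.isnan(last["rmse"])


class TestResidualDiagnostics:
    def test_white_noise_and_no_age_trend(self, small_fit):
        _, chains = small_fit
        out = c.residual_diagnostics(chains, max_lag=5)
        assert out["acf"][0] == pytest.approx(1.0, abs=0.2)
        # short-lag ACF of a well-specified fit stays near zero
        assert np.all(np.abs(out["acf"][2:]) < 0.35)
        lo, hi = out["age_slope_ci"]
        assert lo <= 0.0 <= hi or abs(out["age_slope"]) < 0.05
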