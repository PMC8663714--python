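import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from recruitlag import dlm_model as dm
from recruitlag import lag_features as lf
from recruitlag import synthetic_data as sd
from recruitlag.campaign_io import CHANNELS

from conftest import make_schedule


def normal_equations(X, y):
    """Brute-force OLS oracle: solve (X'X) beta = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def random_instance(rng, T=30, p=3):
    X = np.column_stack([np.ones(T), rng.normal(size=(T, p))])
    beta = rng.normal(size=p + 1)
    y = X @ beta + rng.normal(size=T)
    cols = ["intercept"] + [f"z{i}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y


class TestFitDlm:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            design, y = random_instance(rng, T=int(rng.integers(10, 50)), p=int(rng.integers(1, 4)))
            fit = dm.fit_dlm(design, y)
            np.testing.assert_allclose(
                fit.params.to_numpy(), normal_equations(design.to_numpy(), y), rtol=1e-8
            )

    def test_noiseless_data_recovered_exactly(self, montreal_sim):
        cfg, sch, _ = montreal_sim
        design = lf.build_design(sch, cfg.lag_spec)
        truth = np.array([cfg.alpha] + [cfg.beta[ch] for ch in CHANNELS])
        fit = dm.fit_dlm(design, design.to_numpy() @ truth)
        np.testing.assert_allclose(fit.params.to_numpy(), truth, rtol=1e-8)
        assert fit.r2 == pytest.approx(1.0)

    def test_intercept_only_estimates_mean(self):
        y = np.array([1.0, 4.0, 7.0, 2.0])
        fit = dm.fit_dlm(pd.DataFrame({"intercept": np.ones(4)}), y)
        assert fit.params["intercept"] == pytest.approx(y.mean())
        assert fit.r2 == pytest.approx(0.0)

    def test_residuals_orthogonal_to_design(self, montreal_sim):
        cfg, sch, daily = montreal_sim
        design = lf.build_design(sch, cfg.lag_spec)
        fit = dm.fit_dlm(design, daily["recruits"])
        scale = np.abs(daily["recruits"].to_numpy()).sum()
        assert abs(fit.resid.sum()) < 1e-8 * scale
        proj = design.to_numpy().T @ fit.resid
        np.testing.assert_allclose(proj, 0, atol=1e-8 * scale)

    def test_matches_statsmodels_inference(self, montreal_sim):
        cfg, sch, daily = montreal_sim
        design = lf.build_design(sch, cfg.lag_spec)
        fit = dm.fit_dlm(design, daily["recruits"])
        res = sm.OLS(daily["recruits"].to_numpy(), design.to_numpy()).fit()
        np.testing.assert_allclose(fit.bse.to_numpy(), res.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), res.pvalues, rtol=1e-10, atol=1e-12)
        # our AIC counts the error variance as a parameter; statsmodels does not
        assert fit.aic == pytest.approx(res.aic + 2.0)
        assert fit.bic == pytest.approx(res.bic + math.log(fit.n_obs))
        assert fit.r2 == pytest.approx(res.rsquared)
        assert fit.adj_r2 == pytest.approx(res.rsquared_adj)

    def test_r2_never_drops_when_adding_a_regressor(self):
        rng = np.random.default_rng(5)
        design, y = random_instance(rng, T=40, p=2)
        base = dm.fit_dlm(design[["intercept", "z0"]], y)
        full = dm.fit_dlm(design, y)
        assert full.r2 >= base.r2 - 1e-12
        assert full.adj_r2 <= full.r2

    def test_criteria_invariant_ranking_under_likelihood_constant(self):
        # shifting the outcome rescales the likelihood constant identically
        # across candidate models, leaving criterion differences unchanged
        rng = np.random.default_rng(6)
        design, y = random_instance(rng, T=40, p=2)
        d_aic = dm.fit_dlm(design, y).aic - dm.fit_dlm(design[["intercept", "z0"]], y).aic
        y2 = y + 1000.0
        d_aic2 = dm.fit_dlm(design, y2).aic - dm.fit_dlm(design[["intercept", "z0"]], y2).aic
        assert d_aic == pytest.approx(d_aic2, abs=1e-6)

    def test_rank_deficiency_names_collinear_columns(self):
        X = pd.DataFrame(
            {"intercept": np.ones(20), "a": np.arange(20.0), "b": 2 * np.arange(20.0)}
        )
        with pytest.raises(ValueError, match="collinear"):
            dm.fit_dlm(X, np.arange(20.0))

    def test_underdetermined_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="n_obs"):
            dm.fit_dlm(X, np.zeros(3))


class TestPredictDaily:
    def test_zero_design_predicts_intercept(self):
        y = np.array([2.0, 3.0, 4.0, 7.0])
        design = pd.DataFrame({"intercept": np.ones(4), "z": [0.0, 1.0, 0.0, 2.0]})
        fit = dm.fit_dlm(design, y)
        zero = pd.DataFrame({"intercept": np.ones(3), "z": np.zeros(3)})
        np.testing.assert_allclose(dm.predict_daily(fit, zero), fit.params["intercept"])

    def test_training_predictions_preserve_outcome_mean(self, montreal_sim):
        cfg, sch, daily = montreal_sim
        design = lf.build_design(sch, cfg.lag_spec)
        fit = dm.fit_dlm(design, daily["recruits"])
        pred = dm.predict_daily(fit, design)
        np.testing.assert_allclose(pred, fit.fitted, atol=1e-10)
        assert pred.mean() == pytest.approx(daily["recruits"].mean())

    def test_held_out_design_matches_matrix_product(self, montreal_sim):
        cfg, sch, daily = montreal_sim
        design = lf.build_design(sch, cfg.lag_spec)
        fit = dm.fit_dlm(design, daily["recruits"])
        new_sch = sd.generate_schedule(cfg, seed=77)
        new_design = lf.build_design(new_sch, cfg.lag_spec)
        np.testing.assert_allclose(
            dm.predict_daily(fit, new_design),
            new_design.to_numpy() @ fit.params.to_numpy(),
        )

    def test_column_mismatch_rejected(self, montreal_sim):
        cfg, sch, daily = montreal_sim
        design = lf.build_design(sch, cfg.lag_spec)
        fit = dm.fit_dlm(design, daily["recruits"])
        with pytest.raises(ValueError, match="columns"):
            dm.predict_daily(fit, design[list(design.columns[:-1])])


class TestCampaignEffect:
    @staticmethod
    def _fit_with(beta_letters=106.5, beta_wide=163.6):
        spec = lf.LagSpec.published()
        sch = make_schedule(
            {"letters": np.eye(40)[2], "wide_media": np.eye(40)[5] + np.eye(40)[20]}, T=40
        )
        design = lf.build_design(sch, spec)
        cols = ["intercept", "letters_lag15", "wide_media_lag2"]
        truth = pd.Series(0.0, index=design.columns)
        truth[["intercept", "letters_lag15", "wide_media_lag2"]] = [4.3, beta_letters, beta_wide]
        y = design.to_numpy() @ truth.to_numpy() + 0.0
        return dm.fit_dlm(design[cols], y[: len(design)]), spec

    def test_letter_campaign_total_and_daily_profile(self):
        fit, spec = self._fit_with()
        eff = dm.campaign_effect(fit, spec, "letters")
        assert eff.total == pytest.approx(106.5)
        np.testing.assert_allclose(eff.profile, np.full(15, 106.5 / 15), rtol=1e-9)
        assert eff.profile[0] == pytest.approx(7.1, abs=0.01)

    def test_wide_media_two_day_split(self):
        fit, spec = self._fit_with()
        eff = dm.campaign_effect(fit, spec, "wide_media")
        np.testing.assert_allclose(eff.profile, [81.8, 81.8], atol=1e-9)

    def test_profile_sums_exactly_to_total(self):
        fit, spec = self._fit_with(beta_letters=13.7)
        eff = dm.campaign_effect(fit, spec, "letters")
        assert eff.profile.sum() == pytest.approx(eff.total, rel=1e-12)

    def test_zero_coefficient_gives_zero_effect(self):
        fit, spec = self._fit_with(beta_letters=0.0)
        assert dm.campaign_effect(fit, spec, "letters").total == pytest.approx(0.0, abs=1e-9)

    def test_semilog_channel_requires_proportional_form(self, montreal_sim):
        cfg, sch, daily = montreal_sim
        fit = dm.fit_dlm(lf.build_design(sch, cfg.lag_spec), daily["recruits"])
        with pytest.raises(ValueError, match="proportional"):
            dm.campaign_effect(fit, cfg.lag_spec, "paid_fb_reach")
        beta = fit.params["paid_fb_reach_log_lag2"]
        assert dm.proportional_effect(fit, cfg.lag_spec, "paid_fb_reach", 0.1) == pytest.approx(
            beta * math.log(1.1)
        )


class TestSelectLags:
    def test_single_channel_lag_one_truth_found_by_scan(self):
        rng = np.random.default_rng(0)
        T = 60
        x = (rng.random(T) < 0.2).astype(float)
        sch = make_schedule({"wide_media": x}, T=T)
        design = lf.build_design(sch, lf.LagSpec.uniform(1))
        y = 3.0 + 20.0 * design["wide_media_lag1"].to_numpy() + rng.normal(0, 0.3, T)
        res = dm.select_lags(sch, y)
        assert res.spec["wide_media"].lag == 1
        assert res.active_channels == ["wide_media"]

    def test_constant_outcome_ties_break_to_smallest_lag(self):
        sch = make_schedule({"snowball": np.eye(30)[4]}, T=30)
        res = dm.select_lags(sch, np.full(30, 5.0))
        assert res.spec["snowball"].lag == 1

    def test_criteria_table_matches_full_fit(self, montreal_sim):
        # the fast search path and fit_dlm must agree on AIC/BIC/R2
        cfg, sch, daily = montreal_sim
        res = dm.select_lags(sch, daily["recruits"])
        assert res.fit.aic == pytest.approx(
            res.table.set_index(["pass", "channel", "lag"]).loc[
                (res.n_passes, res.active_channels[-1], res.spec[res.active_channels[-1]].lag),
                "aic",
            ],
            abs=1e-6,
        )
        assert res.converged

    def test_exhaustive_grid_agrees_with_profiling_on_small_problem(self):
        rng = np.random.default_rng(9)
        T = 80
        sch = make_schedule(
            {
                "wide_media": (rng.random(T) < 0.1).astype(float),
                "snowball": (rng.random(T) < 0.1).astype(float),
            },
            T=T,
        )
        spec_true = lf.LagSpec.uniform(1).replace("wide_media", 3).replace("snowball", 2)
        design = lf.build_design(sch, spec_true)
        y = (
            2.0
            + 30.0 * design[lf.column_name("wide_media", spec_true["wide_media"])].to_numpy()
            + 15.0 * design[lf.column_name("snowball", spec_true["snowball"])].to_numpy()
            + rng.normal(0, 0.3, T)
        )
        prof = dm.select_lags(sch, y, lag_range=range(1, 7))
        grid = dm.select_lags(
            sch, y, strategy="exhaustive_capped",
            candidate_sets={"wide_media": range(1, 7), "snowball": range(1, 7)},
        )
        assert grid.spec["wide_media"].lag == prof.spec["wide_media"].lag == 3
        assert grid.spec["snowball"].lag == prof.spec["snowball"].lag == 2

    def test_misaligned_outcome_rejected(self, montreal_sim):
        _, sch, _ = montreal_sim
        with pytest.raises(ValueError, match="length"):
            dm.select_lags(sch, np.zeros(10))
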