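import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import geotree as gt
from geotree.mlm import _RemlCore, fit_lm, load_fit


def _null_frame(seed, n=400):
    p = gt.SimulationParams(n_countries=n, seed=seed, sigma_type=0.0,
                            sigma_stage=0.0, sigma_resid=10.0, share_effects=None)
    panel, truth = gt.generate_panel(p)
    return gt.design_frame(panel.data, truth.assignments)


def _crossed_frame(seed, n=400, **kw):
    p = gt.SimulationParams(n_countries=n, seed=seed, share_effects=None, **kw)
    panel, truth = gt.generate_panel(p)
    return gt.design_frame(panel.data, truth.assignments)


class TestRemlCore:
    def test_balanced_one_way_matches_closed_form(self):
        # textbook oracle: balanced one-way REML equals the ANOVA solution
        # sigma_e^2 = MSW, sigma_a^2 = (MSB - MSW) / m
        rng = np.random.default_rng(0)
        a, m = 6, 25
        groups = np.repeat(np.arange(a), m)
        effects = rng.normal(0, 3.0, a)
        y = 10.0 + effects[groups] + rng.normal(0, 1.5, a * m)
        X = np.ones((a * m, 1))
        core = _RemlCore(y, X, [groups], [a])
        res = scipy.optimize.minimize_scalar(
            lambda lg: core.neg_reml(np.array([lg])), bounds=(-10, 10),
            method="bounded", options={"xatol": 1e-12},
        )
        gamma = np.exp(res.x)
        _, _, rWr, _, _ = core._solve(np.array([gamma]))
        sigma_e = rWr / (a * m - 1)

        gm = y.reshape(a, m).mean(axis=1)
        msw = ((y.reshape(a, m) - gm[:, None]) ** 2).sum() / (a * (m - 1))
        msb = m * ((gm - gm.mean()) ** 2).sum() / (a - 1)
        assert sigma_e == pytest.approx(msw, rel=1e-6)
        assert gamma * sigma_e == pytest.approx((msb - msw) / m, rel=1e-6)


class TestCrossClassifiedFit:
    def test_matches_statsmodels_mixedlm(self, model_frame, mortality_spec):
        import statsmodels.formula.api as smf

        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        df = model_frame.copy()
        df["g"] = 1
        sm_res = smf.mixedlm(
            "ncd_mortality_rate ~ log_gdp_per_capita + urbanization_rate"
            " + neonatal_mortality",
            df, groups="g",
            vc_formula={"t": "0 + C(income_type)", "s": "0 + C(stage)"},
        ).fit(reml=True)
        np.testing.assert_allclose(res.params.to_numpy(),
                                   sm_res.fe_params.values, rtol=1e-4)
        # statsmodels orders variance components alphabetically: s, t
        assert res.var_stage == pytest.approx(float(sm_res.vcomp[0]), rel=1e-3)
        assert res.var_type == pytest.approx(float(sm_res.vcomp[1]), rel=1e-3)
        assert res.var_resid == pytest.approx(float(sm_res.scale), rel=1e-3)
        np.testing.assert_allclose(res.bse.to_numpy(), sm_res.bse_fe.values,
                                   rtol=5e-3)

    def test_null_structure_reduces_to_ols(self):
        import statsmodels.api as sm

        # true-zero variance components: REML lands on the boundary roughly
        # half the time per component and is otherwise a small positive value,
        # so the estimates must be small relative to the residual variance and
        # the fixed effects must reduce to OLS exactly at the boundary
        boundary_hits = 0
        for seed in (11, 12, 13, 14, 15):
            frame = _null_frame(seed)
            spec = gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)
            res = gt.fit_crossed_mlm(frame, spec)
            ratio = max(res.var_type, res.var_stage) / res.var_resid
            assert ratio < 0.10
            X = sm.add_constant(frame[list(gt.DEFAULT_COVARIATES)].to_numpy())
            ols = sm.OLS(frame["ncd_mortality_rate"].to_numpy(), X).fit()
            if ratio < 1e-6:
                boundary_hits += 1
                np.testing.assert_allclose(res.params.to_numpy(), ols.params,
                                           rtol=1e-6)
            else:
                np.testing.assert_allclose(res.params.to_numpy(), ols.params,
                                           rtol=0.05)
        assert boundary_hits >= 1  # the boundary solution does occur

    def test_multistart_criterion_dominates_starts(self, model_frame, mortality_spec):
        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        assert all(res.reml_criterion >= s - 1e-6 for s in res.start_criteria)

    def test_row_permutation_invariance(self, model_frame, mortality_spec):
        res1 = gt.fit_crossed_mlm(model_frame, mortality_spec)
        shuffled = model_frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
        res2 = gt.fit_crossed_mlm(shuffled, mortality_spec)
        np.testing.assert_allclose(res1.params.to_numpy(), res2.params.to_numpy(),
                                   rtol=1e-6)
        assert res1.var_type == pytest.approx(res2.var_type, rel=1e-4)
        assert res1.var_stage == pytest.approx(res2.var_stage, rel=1e-4)

    def test_blups_shrunk_toward_zero(self, model_frame, mortality_spec):
        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        assert abs(res.blups_type.sum()) <= len(res.blups_type) * np.sqrt(res.var_type)
        assert abs(res.blups_stage.sum()) <= len(res.blups_stage) * np.sqrt(
            res.var_stage
        )

    def test_profile_interval_brackets_estimate(self, model_frame, mortality_spec):
        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        lo, hi = res.profile_interval("type", grid=60)
        assert lo <= res.var_type <= hi
        lo_s, hi_s = res.profile_interval("stage", grid=60)
        assert lo_s <= res.var_stage <= hi_s

    def test_singular_design_rejected(self, model_frame):
        frame = model_frame.copy()
        frame["dup"] = frame["urbanization_rate"]
        spec = gt.CrossClassifiedSpec(
            "ncd_mortality_rate", ("urbanization_rate", "dup")
        )
        with pytest.raises(ValueError, match="singular"):
            gt.CrossClassifiedMLM.from_dataframe(frame, spec)

    def test_single_level_factor_rejected(self, model_frame):
        frame = model_frame.copy()
        frame["constant_factor"] = "only"
        spec = gt.CrossClassifiedSpec(
            "ncd_mortality_rate", gt.DEFAULT_COVARIATES,
            factor_b="constant_factor",
        )
        with pytest.raises(ValueError, match="levels"):
            gt.CrossClassifiedMLM.from_dataframe(frame, spec)

    def test_summary_renders(self, model_frame, mortality_spec):
        text = gt.fit_crossed_mlm(model_frame, mortality_spec).summary()
        assert "var(income_type)" in text and "REML" in text


class TestPredict:
    def test_null_vc_predictions_equal_ols_fitted(self):
        # at a boundary optimum (both variance components zero) the BLUPs
        # vanish and prediction reduces exactly to the OLS fitted values
        import statsmodels.api as sm

        spec = gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)
        checked = 0
        for seed in (11, 12, 13, 14, 15):
            frame = _null_frame(seed)
            res = gt.fit_crossed_mlm(frame, spec)
            if max(res.var_type, res.var_stage) / res.var_resid > 1e-8:
                continue
            X = sm.add_constant(frame[list(gt.DEFAULT_COVARIATES)].to_numpy())
            ols_fitted = sm.OLS(frame["ncd_mortality_rate"].to_numpy(), X).fit()
            np.testing.assert_allclose(res.predict(frame),
                                       ols_fitted.fittedvalues, rtol=1e-6)
            checked += 1
        assert checked >= 1

    def test_unseen_level_gets_fixed_part_only(self, model_frame, mortality_spec):
        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        new = model_frame.head(3).copy()
        new["stage"] = 99  # never observed
        pred = res.predict(new)
        cov = res.params.index[1:]
        fixed = (res.params.iloc[0]
                 + new[list(cov)].to_numpy() @ res.params.iloc[1:].to_numpy())
        blup_t = res.blups_type.reindex(new["income_type"]).to_numpy()
        np.testing.assert_allclose(pred, fixed + blup_t, rtol=1e-10)

    def test_group_effects_reduce_training_mse(self):
        frame = _crossed_frame(31, sigma_type=30.0, sigma_stage=20.0,
                               sigma_resid=10.0)
        spec = gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)
        res = gt.fit_crossed_mlm(frame, spec)
        obs = frame["ncd_mortality_rate"].to_numpy()
        full = res.predict(frame)
        cov = res.params.index[1:]
        fixed = (res.params.iloc[0]
                 + frame[list(cov)].to_numpy() @ res.params.iloc[1:].to_numpy())
        assert np.mean((obs - full) ** 2) <= np.mean((obs - fixed) ** 2)

    def test_missing_covariate_rejected(self, model_frame, mortality_spec):
        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        with pytest.raises(ValueError, match="missing covariate"):
            res.predict(model_frame.drop(columns=["urbanization_rate"]))

    def test_serialization_round_trip(self, tmp_path, model_frame, mortality_spec):
        res = gt.fit_crossed_mlm(model_frame, mortality_spec)
        path = tmp_path / "fit.json"
        res.save(path)
        pred = load_fit(path)
        np.testing.assert_allclose(pred.predict(model_frame),
                                   res.predict(model_frame), rtol=1e-12)


class TestLinearBaseline:
    def test_exact_recovery_on_clean_design(self):
        rng = np.random.default_rng(8)
        n = 50
        df = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
        })
        df["y"] = 2.0 + 3.0 * df.x1 - 1.5 * df.x2
        spec = gt.CrossClassifiedSpec("y", ("x1", "x2"))
        lm = fit_lm(df, spec)
        np.testing.assert_allclose(lm.params.to_numpy(), [2.0, 3.0, -1.5],
                                   atol=1e-9)

    def test_zero_variance_covariate_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [5.0] * 4})
        with pytest.raises(ValueError, match="singular"):
            fit_lm(df, gt.CrossClassifiedSpec("y", ("x",)))

    def test_lm_residual_variance_dominates_mlm(self):
        frame = _crossed_frame(41, sigma_type=30.0, sigma_stage=20.0,
                               sigma_resid=10.0)
        spec = gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)
        mlm_res = gt.fit_crossed_mlm(frame, spec)
        lm_res = fit_lm(frame, spec)
        assert lm_res.resid_var >= mlm_res.var_resid


class TestHoldout:
    def test_full_train_fraction_rejected(self, model_frame, mortality_spec):
        with pytest.raises(ValueError, match="train_fraction"):
            gt.holdout_evaluate(model_frame, mortality_spec, train_fraction=1.0)

    def test_reproducible_under_seed(self, model_frame, mortality_spec):
        e1 = gt.holdout_evaluate(model_frame, mortality_spec, seed=3)
        e2 = gt.holdout_evaluate(model_frame, mortality_spec, seed=3)
        assert e1["r2_mlm"] == e2["r2_mlm"]
        assert e1["r2_lm"] == e2["r2_lm"]

    def test_split_sizes(self, model_frame, mortality_spec):
        ev = gt.holdout_evaluate(model_frame, mortality_spec, seed=1)
        n = ev["n_train"] + ev["n_test"]
        assert n == len(model_frame.dropna(subset=["ncd_mortality_rate"]))
        assert ev["n_train"] == pytest.approx(0.7 * n, abs=4)

    def test_null_response_gives_near_zero_r2(self):
        rng = np.random.default_rng(17)
        frame = _null_frame(23, n=600).copy()
        frame["ncd_mortality_rate"] = rng.normal(500.0, 10.0, len(frame))
        spec = gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)
        r2s = [gt.holdout_evaluate(frame, spec, seed=s) for s in range(3)]
        assert all(e["r2_mlm"] <= 0.1 and e["r2_lm"] <= 0.1 for e in r2s)

    def test_mlm_beats_lm_with_strong_crossed_effects(self):
        frame = _crossed_frame(51, n=600, sigma_type=30.0, sigma_stage=20.0,
                               sigma_resid=10.0)
        spec = gt.CrossClassifiedSpec("ncd_mortality_rate", gt.DEFAULT_COVARIATES)
        ev = gt.holdout_evaluate(frame, spec, seed=2)
        assert ev["r2_mlm"] > ev["r2_lm"]

    def test_both_r2_definitions_reported(self, model_frame, mortality_spec):
        ev = gt.holdout_evaluate(model_frame, mortality_spec, seed=9)
        assert {"r2_mlm", "r2_lm", "r2_mlm_sse", "r2_lm_sse"} <= set(ev)
        assert ev["r2_mlm_sse"] <= ev["r2_mlm"] + 1e-9
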