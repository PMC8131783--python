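"""GAMM engine: design construction, penalized fitting, REML oracle
equivalence, information criteria, ranking, and prediction."""

import numpy as np
import pandas as pd
import pytest

from conftest import observations_for
from ursadiet.gamm import (AiccUndefinedError, ConditionGAMM, DesignBundle,
                           ModelSpec, _Block, akaike_weights, build_design,
                           candidate_models, compute_aicc, fit_gamm,
                           predict_curve, rank_models, smooth_summary)
from ursadiet.simulate import StudyConfig


def small_obs(n_years=4, n_bears=5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    sessions = [1.0, 2.0, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0]
    for y in range(2012, 2012 + n_years):
        for b in range(n_bears):
            for s in sessions:
                rows.append({
                    "session": s, "year": y, "bear_id": f"B{b}",
                    "status": "with_young" if (b + y) % 2 else "solitary",
                    "diet1": bool(y % 2), "diet2": not bool(y % 2),
                    "th_htl": float(np.exp(-0.39 + 0.01 * np.sin(s)
                                           + 0.02 * rng.standard_normal())),
                })
    return pd.DataFrame(rows)


class TestDesign:
    def test_single_smooth_block(self):
        bundle = build_design(ModelSpec("m", None, ()), small_obs())
        assert sum(b.kind == "smooth" for b in bundle.blocks) == 1

    def test_by_factor_two_blocks_two_lambdas(self):
        spec = ModelSpec("m", "diet1", ("diet1",))
        bundle = build_design(spec, small_obs())
        smooths = [b for b in bundle.blocks if b.kind == "smooth"]
        assert len(smooths) == 2
        # by-level smooths + 2 random factors = 4 penalty parameters
        assert len(bundle.penalized_blocks()) == 4

    def test_random_block_widths_match_levels(self):
        obs = observations_for(1)
        bundle = build_design(ModelSpec("m", None, ()), obs)
        widths = {b.name: b.width for b in bundle.blocks if b.kind == "random"}
        assert widths == {"year": 7, "bear": 12}

    def test_by_factor_must_be_fixed_term(self):
        with pytest.raises(ValueError, match="fixed"):
            ModelSpec("m", "diet1", ("status",))

    def test_candidate_set_is_thirteen(self):
        specs = candidate_models()
        assert len(specs) == 13
        assert len({s.name for s in specs}) == 13


class TestFitting:
    def test_gaussian_fixed_lambda_matches_generalized_ridge(self):
        """With fixed penalties and identity link, coefficients equal the
        closed form (X'X + S)^-1 X'y."""
        obs = small_obs(n_years=2, n_bears=2).head(20)
        bundle = build_design(ModelSpec("m", None, ()), obs)
        lam = [3.0, 1.5, 0.7]
        fit = fit_gamm(bundle, family="gaussian", lambda_fixed=lam)
        S = bundle.total_penalty(np.array(lam))
        expected = np.linalg.solve(bundle.X.T @ bundle.X + S,
                                   bundle.X.T @ bundle.y)
        assert np.allclose(fit.beta, expected, atol=1e-6)

    def test_constant_response_recovers_log_mean(self):
        obs = small_obs()
        obs["th_htl"] = 0.7
        fit = fit_gamm(build_design(ModelSpec("m", None, ()), obs))
        assert fit.beta[0] == pytest.approx(np.log(0.7), abs=1e-6)
        assert all(sd < 1e-3 for sd in fit.random_sd.values())

    def test_nonpositive_response_rejected(self):
        obs = small_obs()
        obs.loc[0, "th_htl"] = 0.0
        with pytest.raises(ValueError, match="y > 0"):
            fit_gamm(build_design(ModelSpec("m", None, ()), obs))

    def test_reml_matches_mixedlm_oracle(self):
        """Random-intercept Gaussian special case against the
        independent statsmodels MixedLM REML fit."""
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        ngrp, per = 12, 8
        groups = np.repeat(np.arange(ngrp), per)
        y = 2.0 + rng.normal(0, 0.7, ngrp)[groups] + rng.normal(0, 1.0, groups.size)
        X = np.column_stack([np.ones(y.size),
                             (groups[:, None] == np.arange(ngrp)).astype(float)])
        bundle = DesignBundle(
            spec=ModelSpec("ri", None, ()), y=y, X=X,
            blocks=[_Block("fixed", "fixed", 0, 1),
                    _Block("year", "random", 1, 1 + ngrp,
                           penalty=np.eye(ngrp), rank=ngrp)],
            fixed_names=["intercept"], year_levels=list(range(ngrp)),
            bear_levels=[], k=0)
        fit = fit_gamm(bundle, family="gaussian")
        oracle = sm.MixedLM(y, np.ones((y.size, 1)), groups=groups).fit(reml=True)
        assert fit.beta[0] == pytest.approx(oracle.params[0], abs=1e-4)
        assert fit.random_sd["year"] == pytest.approx(
            float(np.sqrt(np.asarray(oracle.cov_re)[0, 0])), abs=1e-3)
        assert np.sqrt(fit.working_scale) == pytest.approx(
            float(np.sqrt(oracle.scale)), abs=1e-3)

    def test_smooth_edf_within_bounds(self):
        fit = fit_gamm(build_design(ModelSpec("m", None, ()), observations_for(1)))
        for b in fit.bundle.blocks:
            if b.kind == "smooth":
                assert 1.0 - 1e-6 <= fit.edf_by_block[b.name] <= b.width + 1e-6


class TestAicc:
    def test_formula(self):
        # AICc = AIC + 2k(k+1)/(n-k-1): k=5, n=100 -> +60/94
        aic = -2 * (-10.0) + 2 * 5
        assert compute_aicc(-10.0, 5, 100) == pytest.approx(aic + 60 / 94)

    def test_large_n_limit(self):
        assert compute_aicc(-10.0, 5, 10**9) == pytest.approx(30.0, abs=1e-6)

    def test_domain_edge(self):
        with pytest.raises(AiccUndefinedError):
            compute_aicc(-10.0, 19, 20)


class TestRanking:
    def test_single_model(self):
        table = rank_models([("only", -100.0)])
        assert table["delta"].iloc[0] == 0.0 and table["weight"].iloc[0] == 1.0

    def test_equal_models_split_weight(self):
        table = rank_models([("a", -5.0), ("b", -5.0)])
        assert np.allclose(table["weight"], 0.5)

    def test_weights_sum_to_one_and_nonincreasing(self):
        rng = np.random.default_rng(2)
        table = rank_models([(f"m{i}", v) for i, v in
                             enumerate(rng.uniform(-50, 50, 11))])
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(table["weight"]) <= 1e-12).all()
        assert table["delta"].iloc[0] == 0.0

    def test_published_delta_list_reproduces_top_weights(self):
        from ursadiet.reference import DELTA_AICC, TOP_TWO_WEIGHTS

        weights = akaike_weights(DELTA_AICC)
        assert tuple(round(w, 1) for w in weights[:2]) == TOP_TWO_WEIGHTS


@pytest.fixture(scope="module")
def by_diet_fit():
    spec = [m for m in candidate_models() if m.smooth_by == "diet1"][0]
    return fit_gamm(build_design(spec, observations_for(1)))


class TestPrediction:
    @pytest.fixture()
    def fit(self, by_diet_fit):
        return by_diet_fit

    def test_ci_brackets_mean(self, fit):
        curves = predict_curve(fit, np.linspace(1, 6, 21), {
            "high": {"status": "solitary", "diet1": True, "diet2": False}})
        assert (curves["lo95"] <= curves["mean"]).all()
        assert (curves["mean"] <= curves["hi95"]).all()

    def test_log_link_preserves_ordering(self, fit):
        grid = np.linspace(1, 6, 21)
        curves = predict_curve(fit, grid, {
            "high": {"status": "solitary", "diet1": True, "diet2": False}})
        eta, _ = fit.linear_predictor(pd.DataFrame({
            "session": grid, "status": "solitary", "diet1": True, "diet2": False,
            "year": -1, "bear_id": ""}))
        assert (np.argsort(eta) == np.argsort(curves["mean"].to_numpy())).all()

    def test_extrapolation_warns(self, fit):
        with pytest.warns(UserWarning, match="session range"):
            predict_curve(fit, [0.5, 7.0])

    def test_smooth_summary_shape(self, fit):
        table = smooth_summary(fit)
        assert len(table) == 2
        assert (table["edf"] > 0).all() and (table["F"] >= 0).all()
        assert table["p"].between(0, 1).all()


class TestEstimatorProtocol:
    def test_clone_and_params_roundtrip(self):
        from sklearn.base import clone

        est = ConditionGAMM(smooth_by="diet1",
                            fixed=("status", "diet1", "status:diet1"), k=6)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(k=4)
        assert est.k == 4
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_fit_predict_score(self, default_observations):
        est = ConditionGAMM(fixed=("status",)).fit(default_observations)
        assert est.converged_
        predictions = est.predict(default_observations)
        assert predictions.shape == (len(default_observations),)
        assert (predictions > 0).all()
        assert est.score(default_observations) > -1e-3
        assert est.aicc_ == est.result_.aicc


class TestRecovery:
    def test_group_offset_in_ci_and_sign(self):
        """The generating reproductive-status offset (-0.025 log scale)
        falls inside the 95% CI in >= 17/20 seeded replicates."""
        seeds = np.random.SeedSequence(2024).spawn(20)
        inside = 0
        for child in seeds:
            seed = int(child.generate_state(1)[0] % 2**31)
            obs = observations_for(seed)
            fit = fit_gamm(build_design(ModelSpec("m", None, ("status",)), obs))
            table = fit.fixed_table().set_index("term")
            beta = table.loc["status (with young)", "beta"]
            se = table.loc["status (with young)", "se"]
            if beta - 1.96 * se <= -0.025 <= beta + 1.96 * se:
                inside += 1
        assert inside >= 17

    def test_generating_model_wins_selection(self):
        """Data generated from a candidate spec at 5x the study's bear
        count: that spec attains the top Akaike weight in >= 70% of 20
        replicates."""
        config = StudyConfig(bears=tuple(f"B{i:02d}" for i in range(60)))
        seeds = np.random.SeedSequence(77).spawn(20)
        wins = 0
        for child in seeds:
            seed = int(child.generate_state(1)[0] % 2**31)
            obs = observations_for(seed, config)
            fits = [fit_gamm(build_design(m, obs)) for m in candidate_models()]
            table = rank_models(fits)
            if table["model"].iloc[0] == "S(Session x Diet1) + RST x Diet1":
                wins += 1
        assert wins >= 14
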