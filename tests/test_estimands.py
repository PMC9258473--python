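"""Estimand-summary tests: percentiles, directional probabilities,
standardization, manipulation checks, blinded subgroup search, OLS cross-check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialforest import (
    BCFConfig,
    GeneratorTruth,
    TrialDataset,
    average_effect,
    fit_bcf,
    frequentist_crosscheck,
    gen_cross_sectional,
    manipulation_check,
    prob_difference,
    standardize,
    subgroup_cutpoint_search,
    summarize_draws,
)
from trialforest.bcf import BCFPosterior


def fake_posterior(tau_1, arm_codes=None, tau_2=None, mu=None, alpha=None):
    """Assemble a posterior object directly from draw matrices."""
    draws, rows = tau_1.shape
    arm_codes = np.zeros(rows, dtype=int) if arm_codes is None else arm_codes
    tau = {1: tau_1}
    if tau_2 is not None:
        tau[2] = tau_2
    return BCFPosterior(
        alpha_draws=np.zeros((draws, rows)) if alpha is None else alpha,
        mu_draws=np.zeros((draws, rows)) if mu is None else mu,
        tau_draws=tau,
        sigma_draws=np.ones(draws),
        sigma_alpha_draws=np.zeros(draws),
        config=BCFConfig(draws=draws),
        unit_labels=list(range(rows)),
        unit_codes=np.arange(rows),
        arm_codes=arm_codes,
        row_index=np.arange(rows),
        moderator_columns=[],
    )


class TestAverageEffect:
    def test_constant_draws(self):
        post = fake_posterior(np.full((200, 10), -0.2))
        s = average_effect(post)
        assert s.mean == -0.2
        assert s.pct_10 == s.pct_90 == s.pct_2_5 == s.pct_97_5 == -0.2
        assert s.direction == -1 and s.prob_direction == 1.0

    def test_normal_draws_match_closed_form_quantile(self):
        rng = np.random.default_rng(0)
        post = fake_posterior(rng.standard_normal((100_000, 1)))
        s = average_effect(post)
        assert s.pct_10 == pytest.approx(-1.2816, abs=0.02)
        assert s.pct_90 == pytest.approx(1.2816, abs=0.02)

    def test_full_subset_equals_row_cate_mean(self):
        rng = np.random.default_rng(1)
        tau = rng.normal(0.3, 0.1, size=(500, 20))
        post = fake_posterior(tau)
        ate = average_effect(post).mean
        per_row = [
            average_effect(post, row_subset=np.arange(20) == i).mean
            for i in range(20)
        ]
        assert ate == pytest.approx(np.mean(per_row), abs=1e-12)

    def test_empty_subset_is_an_error(self):
        post = fake_posterior(np.zeros((10, 5)))
        with pytest.raises(ValueError, match="empty"):
            average_effect(post, row_subset=np.zeros(5, dtype=bool))

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=60))
    def test_percentile_ordering_invariant(self, vals):
        s = summarize_draws(np.asarray(vals))
        assert s.pct_2_5 <= s.pct_10 <= s.pct_90 <= s.pct_97_5
        assert 0.0 <= s.prob_direction <= 1.0


class TestProbDifference:
    def test_separated_draws(self):
        post = fake_posterior(np.full((100, 4), -0.5), tau_2=np.full((100, 4), -0.1))
        assert prob_difference(post, 1, 2, direction=-1) == 1.0

    def test_identical_draws_tie_rule(self):
        tau = np.linspace(-1, 1, 50)[:, None] * np.ones((1, 3))
        post = fake_posterior(tau, tau_2=tau.copy())
        assert prob_difference(post, 1, 2, direction=-1) == 0.5

    def test_direction_probabilities_sum_to_one(self):
        rng = np.random.default_rng(2)
        post = fake_posterior(rng.normal(size=(999, 5)), tau_2=rng.normal(size=(999, 5)))
        p_neg = prob_difference(post, 1, 2, direction=-1)
        p_pos = prob_difference(post, 1, 2, direction=1)
        assert p_neg + p_pos == pytest.approx(1.0)

    def test_unknown_arm_rejected(self):
        post = fake_posterior(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="arm"):
            prob_difference(post, 1, 9)


def two_arm_frame(y0, y1):
    y = np.concatenate([y0, y1])
    return TrialDataset(
        pd.DataFrame(
            {
                "unit": np.arange(y.size),
                "arm": np.repeat([0, 1], [len(y0), len(y1)]),
                "y": y,
            }
        ),
        outcome="y",
        arm="arm",
        unit="unit",
    )


class TestStandardize:
    def test_division_by_pooled_sd(self):
        rng = np.random.default_rng(3)
        ds = two_arm_frame(rng.normal(0, 2.0, 4000), rng.normal(0, 2.0, 4000))
        s = summarize_draws(np.full(100, -1.0))
        out = standardize(s, ds)
        assert out.scale == "standardized"
        assert out.mean == pytest.approx(-0.5, abs=0.02)

    def test_double_standardization_guarded(self):
        ds = two_arm_frame(np.array([0.0, 1, 2]), np.array([1.0, 2, 3]))
        s = standardize(summarize_draws(np.ones(10)), ds)
        with pytest.raises(ValueError, match="already standardized"):
            standardize(s, ds)

    def test_pooled_formula_equal_weighting(self):
        rng = np.random.default_rng(4)
        ds = two_arm_frame(rng.normal(0, 1.0, 20000), rng.normal(0, 3.0, 20000))
        # equal-n arms with s.d. 1 and 3 pool to sqrt((1 + 9) / 2)
        assert ds.pooled_sd() == pytest.approx(np.sqrt(5.0), rel=0.02)


class TestManipulationCheck:
    def test_strong_effect_passes(self):
        ds, _ = gen_cross_sectional(
            500, truth=GeneratorTruth(true_ate_per_arm=(-0.5,)), seed=17
        )
        cfg = BCFConfig(
            n_trees_prognostic=30, n_trees_moderator=12, draws=250, burnin=150, seed=3
        )
        post = fit_bcf(ds, cfg)
        summary, passed = manipulation_check(post, ds)
        assert passed
        assert summary.mean == pytest.approx(-0.5, abs=0.15)

    def test_constant_draw_threshold_rule(self):
        ds = two_arm_frame(np.arange(20.0), np.arange(20.0))
        sd = ds.pooled_sd()
        post = fake_posterior(np.full((100, 40), -0.26 * sd))
        _, passed = manipulation_check(post, ds)
        assert passed
        post2 = fake_posterior(np.full((100, 40), -0.10 * sd))
        # a constant draw has a degenerate interval excluding zero, so the
        # interval rule passes even below the magnitude threshold
        _, passed2 = manipulation_check(post2, ds)
        assert passed2

    def test_null_simulations_mostly_fail(self):
        cfg = BCFConfig(
            n_trees_prognostic=15, n_trees_moderator=8, draws=150, burnin=100, seed=0
        )
        fails = 0
        reps = 10
        for rep in range(reps):
            ds, _ = gen_cross_sectional(
                300, truth=GeneratorTruth(true_ate_per_arm=(0.0,)), seed=100 + rep
            )
            post = fit_bcf(ds, cfg)
            _, passed = manipulation_check(post, ds)
            fails += not passed
        assert fails >= 0.8 * reps


class TestSubgroupSearch:
    def _fit(self, ds, seed=5):
        cfg = BCFConfig(
            n_trees_prognostic=40, n_trees_moderator=10, draws=200, burnin=150,
            seed=seed, keep_moderator_forests=False,
        )
        return fit_bcf(ds, cfg)

    def test_control_outcome_jump_located(self):
        rng = np.random.default_rng(21)
        n = 600
        w = rng.normal(0.0, 1.0, n)
        arm = rng.integers(0, 2, n)
        y = 1.0 * (w > 0.0) + 0.3 * rng.standard_normal(n)
        frame = pd.DataFrame({"unit": np.arange(n), "arm": arm, "y": y, "w": w})
        ds = TrialDataset(frame, outcome="y", arm="arm", unit="unit",
                          covariates=["w"], moderators=["w"])
        post = self._fit(ds)
        cut, labels, objective, weak = subgroup_cutpoint_search(ds, post, "w")
        assert abs(cut - 0.0) <= 0.2
        assert not weak
        assert set(labels) == {"above", "below"}

    def test_unrelated_moderator_flags_weak_signal(self):
        rng = np.random.default_rng(22)
        n = 500
        frame = pd.DataFrame(
            {
                "unit": np.arange(n),
                "arm": rng.integers(0, 2, n),
                "y": rng.standard_normal(n),
                "w": rng.normal(size=n),
            }
        )
        ds = TrialDataset(frame, outcome="y", arm="arm", unit="unit",
                          covariates=["w"], moderators=["w"])
        post = self._fit(ds)
        with pytest.warns(UserWarning, match="little control-outcome separation"):
            _, _, objective, weak = subgroup_cutpoint_search(ds, post, "w")
        assert weak
        assert objective < 0.3 * np.std(ds.y)

    def test_blinding_to_effect_draws(self):
        ds, _ = gen_cross_sectional(400, seed=2)
        post = self._fit(ds)
        cut, _, _, _ = subgroup_cutpoint_search(ds, post, "mindset_product")
        rng = np.random.default_rng(0)
        for k in post.tau_draws:
            post.tau_draws[k] = rng.permutation(post.tau_draws[k], axis=0)
        cut2, _, _, _ = subgroup_cutpoint_search(ds, post, "mindset_product")
        assert cut == cut2  # exact: the search never reads tau draws


class TestFrequentistCrosscheck:
    def test_recovers_generator_effect(self):
        ds, _ = gen_cross_sectional(
            2000, truth=GeneratorTruth(true_ate_per_arm=(0.4,)), seed=31
        )
        out = frequentist_crosscheck(ds, covariates=["fixed_mindset", "stress_mindset"])
        assert out["coef"] == pytest.approx(0.4, abs=0.07)

    def test_no_covariates_equals_difference_in_means(self):
        rng = np.random.default_rng(5)
        ds = two_arm_frame(rng.normal(0, 1, 50), rng.normal(0.5, 1, 50))
        out = frequentist_crosscheck(ds)
        y, z = ds.y, ds.arm_codes
        assert out["coef"] == pytest.approx(y[z == 1].mean() - y[z == 0].mean(), abs=1e-10)

    def test_null_calibration(self):
        rejections = 0
        reps = 20
        for rep in range(reps):
            ds, _ = gen_cross_sectional(
                300, truth=GeneratorTruth(true_ate_per_arm=(0.0,)), seed=400 + rep
            )
            out = frequentist_crosscheck(ds)
            rejections += abs(out["tvalue"]) > 1.96
        assert rejections <= 0.1 * reps + 1

    def test_collinear_covariate_dropped(self):
        rng = np.random.default_rng(6)
        n = 100
        frame = pd.DataFrame(
            {
                "unit": np.arange(n),
                "arm": rng.integers(0, 2, n),
                "y": rng.standard_normal(n),
                "x1": rng.standard_normal(n),
            }
        )
        frame["x2"] = 2.0 * frame["x1"]
        ds = TrialDataset(frame, outcome="y", arm="arm", unit="unit",
                          covariates=["x1", "x2"])
        with pytest.warns(UserWarning, match="collinear"):
            out = frequentist_crosscheck(ds, covariates=["x1", "x2"])
        assert out["dropped"] == ["x2"]

    def test_agreement_with_bayesian_ate(self):
        ds, _ = gen_cross_sectional(
            1500, truth=GeneratorTruth(true_ate_per_arm=(0.5,)), seed=41
        )
        cfg = BCFConfig(
            n_trees_prognostic=30, n_trees_moderator=12, draws=250, burnin=200,
            seed=2, keep_moderator_forests=False,
        )
        post = fit_bcf(ds, cfg)
        ols = frequentist_crosscheck(ds)
        assert post.ate_draws(1).mean() == pytest.approx(ols["coef"], abs=0.1)
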