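"""Tree-machinery tests: routing, MH correctness against enumeration,
conjugate closed forms, and the sum-of-trees representation invariant."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from trialforest.trees import (
    CovariateSet,
    DepthPrior,
    Forest,
    ForestPrior,
    ProposalProbs,
    SplitRule,
    Tree,
    VariancePrior,
    mh_tree_update,
    predict_tree,
    sample_error_variance,
)


def make_cov(values, name="x0"):
    return CovariateSet(pd.DataFrame({name: values}), n_cutpoints=10)


class TestPredictTree:
    def test_stump_returns_leaf_value(self):
        tree = Tree()
        tree.eta[0, 0] = 0.7
        assert predict_tree(tree, np.array([123.0])) == pytest.approx(0.7)

    def test_routing_and_boundary_convention(self):
        # split on variable 0 at 0.5; left iff value < threshold
        tree = Tree()
        lid, rid = tree.add_children(0, SplitRule(0, threshold=0.5))
        tree.eta[lid, 0] = -1.0
        tree.eta[rid, 0] = 1.0
        assert predict_tree(tree, np.array([0.2])) == -1.0
        assert predict_tree(tree, np.array([0.5])) == 1.0  # boundary goes right
        assert predict_tree(tree, np.array([0.9])) == 1.0

    def test_missing_variable_is_an_error(self):
        tree = Tree()
        tree.add_children(0, SplitRule(2, threshold=0.0))
        with pytest.raises(ValueError, match="missing variable"):
            predict_tree(tree, np.array([1.0]))


class TestErrorVariance:
    def test_matches_inverse_gamma_closed_form(self, rng):
        resid = np.array([1.0, -2.0, 0.5, 1.5, -1.0, 2.0, -0.5, 0.25])
        prior = VariancePrior(nu=3.0, lam=0.8)
        draws = np.array(
            [sample_error_variance(resid, prior, rng) for _ in range(10_000)]
        )
        shape = 0.5 * (prior.nu + resid.size)
        scale = 0.5 * (prior.nu * prior.lam + resid @ resid)
        expected_mean = scale / (shape - 1.0)  # inverse-gamma mean
        assert draws.mean() == pytest.approx(expected_mean, rel=0.02)

    def test_scale_equivariance(self, rng):
        resid = np.linspace(-2, 2, 50)
        prior = VariancePrior(nu=3.0, lam=1e-6)
        lo = np.mean([np.sqrt(sample_error_variance(resid, prior, rng)) for _ in range(2000)])
        hi = np.mean([np.sqrt(sample_error_variance(3 * resid, prior, rng)) for _ in range(2000)])
        assert hi / lo == pytest.approx(3.0, rel=0.05)

    def test_empty_residuals_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_error_variance(np.array([]), VariancePrior(), rng)


def _two_state_log_posteriors(resid, sigma, prior, n_rules):
    """Enumerate the stump/one-split tree space on a binary covariate.

    With 4 rows of a single binary covariate and the quantile cut grid, the
    only valid split is at threshold 1 (x = 0 rows go left); deeper trees are
    impossible.  Returns (log pi(stump), log pi(split)) up to a shared
    constant, with the split-rule probability included in the prior.
    """
    s2 = prior.leaf_scale**2
    sigma2 = sigma**2

    def leaf_ml(r):
        n = len(r)
        S = np.sum(r)
        return 0.5 * np.log(sigma2 / (sigma2 + n * s2)) + 0.5 * s2 * S**2 / (
            sigma2 * (sigma2 + n * s2)
        )

    p_root = prior.depth_prior.p_split(0)
    p_child = prior.depth_prior.p_split(1)
    left, right = resid[:2], resid[2:]
    log_stump = math.log(1 - p_root) + leaf_ml(resid)
    # every grid threshold lies in (0, 1] so all n_rules candidate rules
    # induce the same partition; the uniform rule probability 1/n_rules is
    # aggregated over those n_rules equivalent rules and cancels
    log_split = (
        math.log(p_root)
        + 2 * math.log(1 - p_child)
        + leaf_ml(left)
        + leaf_ml(right)
    )
    return log_stump, log_split


class TestMHStationaryDistribution:
    def test_matches_enumerated_posterior(self):
        """Total variation between MCMC occupancy and the enumerated two-state
        posterior is below 0.05 — a brute-force detailed-balance check."""
        x = np.array([0.0, 0.0, 1.0, 1.0])
        resid = np.array([-1.2, -0.8, 0.9, 1.1])
        cov = make_cov(x)
        grid = cov.cutpoints[0]
        assert np.all((grid > 0) & (grid <= 1))  # all rules give one partition
        sigma = 1.0
        prior = ForestPrior(
            leaf_scale=1.0, depth_prior=DepthPrior(0.5, 2.0), min_leaf=1
        )
        log_stump, log_split = _two_state_log_posteriors(
            resid, sigma, prior, n_rules=int(cov.n_rules[0])
        )
        m = max(log_stump, log_split)
        w = np.exp([log_stump - m, log_split - m])
        target = w / w.sum()

        rng = np.random.default_rng(42)
        tree = Tree()
        counts = np.zeros(2)
        burn, sweeps = 500, 10_000
        for i in range(burn + sweeps):
            mh_tree_update(tree, cov, resid, sigma, prior, rng,
                           resample_leaf_values=False)
            if i >= burn:
                counts[0 if tree.n_leaves() == 1 else 1] += 1
        occupancy = counts / counts.sum()
        tv = 0.5 * np.abs(occupancy - target).sum()
        assert tv < 0.05, (occupancy, target)

    def test_zero_variance_residuals_collapse_to_stump(self):
        """With no signal, a conservative depth prior plus the marginal
        likelihood's Occam factor keep the chain on the stump state."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        resid = np.zeros(40)
        cov = make_cov(x)
        prior = ForestPrior(
            leaf_scale=1.0, depth_prior=DepthPrior(0.25, 3.0), min_leaf=2
        )
        tree = Tree()
        stumps = 0
        for i in range(500):
            mh_tree_update(tree, cov, resid, 1.0, prior, rng,
                           resample_leaf_values=False)
            stumps += tree.n_leaves() == 1
        assert stumps / 500 > 0.9

    def test_grow_rejected_when_children_too_small(self):
        # 4 rows, min_leaf 5: every grow proposal must be rejected
        x = np.array([0.0, 0.0, 1.0, 1.0])
        cov = make_cov(x)
        prior = ForestPrior(leaf_scale=1.0, min_leaf=5)
        rng = np.random.default_rng(3)
        tree = Tree()
        for _ in range(200):
            mh_tree_update(tree, cov, np.array([-3.0, -3.0, 3.0, 3.0]), 1.0,
                           prior, rng, resample_leaf_values=False)
        assert tree.n_leaves() == 1


class TestBackfitting:
    def test_stump_forest_matches_conjugate_posterior(self, rng):
        """A forest of stumps on data with a constant mean is a conjugate
        normal mean model: f ~ N(0, m s^2) prior, known sigma."""
        n, m, s, sigma = 60, 8, 0.4, 0.7
        y = rng.normal(2.0, sigma, n)
        cov = make_cov(np.zeros(n))  # no split candidates: trees stay stumps
        prior = ForestPrior(leaf_scale=s, min_leaf=5)
        forest = Forest(cov, m, prior)
        prior_var = m * s * s
        post_var = 1.0 / (1.0 / prior_var + n / sigma**2)
        post_mean = post_var * n * y.mean() / sigma**2

        resid = y.copy()
        means = []
        for i in range(1500):
            resid = forest.backfit_sweep(resid, sigma, rng)
            if i >= 300:
                means.append(forest.prediction().mean())
        mc = np.mean(means)
        assert mc == pytest.approx(post_mean, abs=3 * np.sqrt(post_var / 50))

    def test_prediction_identity_after_sweeps(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = np.sin(2 * x) + 0.2 * rng.standard_normal(n)
        cov = make_cov(x)
        forest = Forest(cov, 10, ForestPrior(leaf_scale=0.3, min_leaf=5))
        resid = y.copy()
        for _ in range(30):
            resid = forest.backfit_sweep(resid, 0.5, rng)
        total = sum(st.raw for st in forest.states)
        np.testing.assert_allclose(forest.raw_prediction(), total, rtol=0, atol=0)
        np.testing.assert_allclose(y - forest.prediction(), resid, atol=1e-10)

    def test_shrinkage_limit_small_leaf_scale(self, rng):
        n = 100
        y = rng.normal(0.0, 1.0, n)
        y -= y.mean()
        cov = make_cov(rng.normal(size=n))
        forest = Forest(cov, 5, ForestPrior(leaf_scale=1e-4, min_leaf=5))
        resid = y.copy()
        for _ in range(50):
            resid = forest.backfit_sweep(resid, 1.0, rng)
        assert np.max(np.abs(forest.prediction())) < 0.01

    def test_nonfinite_residuals_rejected(self, rng):
        cov = make_cov(np.arange(10.0))
        forest = Forest(cov, 2, ForestPrior())
        bad = np.full(10, np.nan)
        with pytest.raises(ValueError):
            forest.backfit_sweep(bad, 1.0, rng)


class TestReproducibility:
    def test_same_seed_same_chain(self):
        x = np.linspace(-2, 2, 50)
        y = x**2
        cov = make_cov(x)

        def run(seed):
            rng = np.random.default_rng(seed)
            forest = Forest(cov, 6, ForestPrior(leaf_scale=0.5, min_leaf=5))
            resid = y.copy()
            for _ in range(40):
                resid = forest.backfit_sweep(resid, 0.5, rng)
            return forest.prediction()

        np.testing.assert_array_equal(run(9), run(9))
        assert not np.array_equal(run(9), run(10))


class TestCovariateSet:
    def test_categorical_rules_and_unseen_levels(self):
        frame = pd.DataFrame({"g": ["a", "b", "c", "a", "b", "c"]})
        cov = CovariateSet(frame)
        assert cov.is_categorical[0]
        assert cov.n_rules[0] == 2**3 - 2
        values, unseen = cov.encode_like(pd.DataFrame({"g": ["b", "zzz"]}))
        assert values[0, 0] == 1.0
        assert unseen[1, 0] and not unseen[0, 0]

    @given(st.integers(2, 40))
    def test_numeric_grid_never_empties_a_side(self, n):
        v = np.linspace(0, 1, n)
        cov = make_cov(v)
        grid = cov.cutpoints[0]
        assert np.all(grid > v.min())
        assert np.all(grid <= v.max())


class TestPriors:
    def test_depth_prior_validation(self):
        with pytest.raises(ValueError):
            DepthPrior(1.5, 2.0)
        with pytest.raises(ValueError):
            DepthPrior(0.95, -1.0)

    def test_proposal_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ProposalProbs(0.5, 0.5, 0.5)
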