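import numpy as np
import pytest

from driftrar import (
    DesignSpec,
    PolicyConfig,
    PosteriorCounts,
    cflgi_probabilities,
    cr_policy,
    dbcd_probabilities,
    flgi_probabilities,
    make_policy,
    prob_best,
    rsihr_target,
    ts_probabilities,
)


def counts_from(s, f):
    return PosteriorCounts(np.asarray(s, float), np.asarray(f, float))


class TestCR:
    @pytest.mark.parametrize("K", [1, 2, 4])
    def test_uniform_and_data_independent(self, K):
        uniform = np.full(K + 1, 1.0 / (K + 1))
        np.testing.assert_allclose(cr_policy(1, counts_from([1] * (K + 1), [1] * (K + 1))), uniform)
        np.testing.assert_allclose(
            cr_policy(3, counts_from(range(2, K + 3), range(5, K + 6))), uniform
        )


class TestProbBest:
    def test_symmetric_posteriors(self, rng):
        pb = prob_best(counts_from([1, 1], [1, 1]), 40_000, rng)
        assert abs(pb[0] - 0.5) < 3 * np.sqrt(0.25 / 40_000)

    def test_beta21_vs_beta12(self, rng):
        # P(p1 > p0) for Beta(2,1) vs Beta(1,2) is 5/6 in closed form
        pb = prob_best(counts_from([1, 2], [2, 1]), 60_000, rng)
        se = np.sqrt(5 / 6 * 1 / 6 / 60_000)
        assert abs(pb[1] - 5 / 6) < 3 * se

    def test_three_identical(self, rng):
        pb = prob_best(counts_from([2, 2, 2], [3, 3, 3]), 60_000, rng)
        assert np.all(np.abs(pb - 1 / 3) < 3 * np.sqrt(2 / 9 / 60_000))
        assert pb.sum() == pytest.approx(1.0)


class TestThompson:
    def setup_method(self):
        self.design = DesignSpec(K=1, T=100, J=5, b=20)
        self.config = PolicyConfig(rule="TS", ts_mc_draws=40_000)

    def test_first_block_is_uniform_for_any_data(self, rng):
        pi = ts_probabilities(1, counts_from([9, 2], [2, 9]), self.design, self.config, rng)
        np.testing.assert_allclose(pi, [0.5, 0.5])

    def test_exponent_one_is_identity_on_prob_best(self):
        state = counts_from([2, 1], [1, 2])
        pb = prob_best(state, 60_000, np.random.default_rng(3))
        pi = ts_probabilities(
            2, state, self.design, self.config, np.random.default_rng(3), c=1.0
        )
        np.testing.assert_allclose(pi, pb, atol=5e-3)

    def test_symmetric_counts_give_uniform(self, rng):
        pi = ts_probabilities(3, counts_from([4, 4], [7, 7]), self.design, self.config, rng)
        assert abs(pi[0] - 0.5) < 0.02

    def test_large_exponent_approaches_point_mass(self, rng):
        pi = ts_probabilities(
            2, counts_from([8, 2], [2, 8]), self.design, self.config, rng, c=50.0
        )
        assert pi[0] > 0.999

    def test_zero_exponent_is_uniform(self, rng):
        pi = ts_probabilities(
            2, counts_from([8, 2], [2, 8]), self.design, self.config, rng, c=0.0
        )
        np.testing.assert_allclose(pi, [0.5, 0.5])


class TestRSIHRTarget:
    def test_equal_rates_balanced(self):
        np.testing.assert_allclose(rsihr_target(np.array([0.4, 0.4]), 1), [0.5, 0.5])

    def test_sqrt_rule_value(self):
        rho = rsihr_target(np.array([0.1, 0.9]), 1)
        assert rho[1] == pytest.approx(0.75)

    def test_plain_ratio_variant(self):
        rho = rsihr_target(np.array([0.3, 0.7]), 1, form="ratio")
        assert rho[1] == pytest.approx(0.7)

    def test_monotone_in_p1(self):
        grid = np.linspace(0.05, 0.95, 19)
        rho1 = [rsihr_target(np.array([0.4, p1]), 1)[1] for p1 in grid]
        assert np.all(np.diff(rho1) > 0)
        assert np.all([0 < r < 1 for r in rho1])

    def test_out_of_range_estimates_clamped(self):
        with pytest.warns(UserWarning):
            rho = rsihr_target(np.array([0.0, 1.0]), 1)
        assert rho.sum() == pytest.approx(1.0)

    def test_multiarm_numerical_solution(self):
        rho = rsihr_target(np.array([0.3, 0.7, 0.3]), 2)
        assert rho.sum() == pytest.approx(1.0)
        assert np.all(rho >= 0.05 - 1e-9)
        # failures are minimised by moving mass toward the best arm
        assert rho[1] == np.max(rho)
        # fixed-variance constraint (against equal allocation) respected
        v = np.array([p * (1 - p) for p in (0.3, 0.7, 0.3)])
        assert v[0] / rho[0] + v[1] / rho[1] <= 3 * (v[0] + v[1]) + 1e-6


class TestDBCD:
    def setup_method(self):
        self.config = PolicyConfig(rule="RSIHR", gamma=2.0)

    def test_fixed_point(self):
        # x == rho: with equal rates the target is (.5,.5); 10 patients each
        counts = counts_from([4, 4], [8, 8])
        pi = dbcd_probabilities(2, counts, np.array([0.4, 0.4]), self.config)
        np.testing.assert_allclose(pi, [0.5, 0.5])

    def test_hand_computed_value(self):
        # p = (0.9, 0.4) gives rho = (0.6, 0.4); x = (0.5, 0.5), gamma = 2
        counts = counts_from([6, 5], [6, 7])  # 10 patients per arm
        pi = dbcd_probabilities(2, counts, np.array([0.9, 0.4]), self.config)
        np.testing.assert_allclose(pi, [0.864 / 1.12, 0.256 / 1.12], atol=1e-10)

    def test_first_block_uniform_from_prior_means(self):
        design = DesignSpec(K=1, T=100, J=5, b=20)
        counts = PosteriorCounts.initial(design)
        pi = dbcd_probabilities(1, counts, counts.posterior_mean, self.config)
        np.testing.assert_allclose(pi, [0.5, 0.5])


def enumerate_flgi(s, f, b, table):
    """Exact FLGI probabilities by exhaustive rollout-path enumeration:
    branch on greedy ties (uniform weight) and on the posterior-predictive
    virtual outcome of each chosen arm."""
    A = len(s)
    alloc = np.zeros(A)

    def recurse(s, f, weight, depth):
        nonlocal alloc
        if depth == b:
            return
        gi = np.array([table.value(s[k], f[k]) for k in range(A)])
        winners = np.flatnonzero(gi == gi.max())
        for k in winners:
            w = weight / winners.size
            alloc[k] += w  # one patient to arm k at this depth
            p = s[k] / (s[k] + f[k])
            s2, f2 = list(s), list(f)
            s2[k] += 1
            recurse(tuple(s2), tuple(f), w * p, depth + 1)
            f2[k] += 1
            recurse(tuple(s), tuple(f2), w * (1 - p), depth + 1)

    recurse(tuple(s), tuple(f), 1.0, 0)
    return alloc / b


class TestFLGI:
    def config(self, table, reps=100):
        return PolicyConfig(rule="FLGI", gi_table=table, flgi_mc_reps=reps)

    def test_symmetric_prior_single_patient(self, gi_table_small, rng):
        design = DesignSpec(K=1, T=5, J=5, b=1)
        counts = counts_from([1, 1], [1, 1])
        pi = flgi_probabilities(
            2, counts, design, self.config(gi_table_small, reps=4000), rng
        )
        assert abs(pi[0] - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_dominant_arm_takes_whole_block(self, gi_table_small, rng):
        # exchange + monotonicity keep arm 1's index maximal on every path
        design = DesignSpec(K=1, T=10, J=5, b=2)
        counts = counts_from([1, 2], [2, 1])
        pi = flgi_probabilities(2, counts, design, self.config(gi_table_small), rng)
        np.testing.assert_allclose(pi, [0.0, 1.0])

    @pytest.mark.parametrize("s,f,b", [((1, 1), (1, 1), 2), ((2, 1), (1, 1), 3), ((1, 2), (2, 2), 3)])
    def test_against_exhaustive_enumeration(self, gi_table_small, s, f, b):
        exact = enumerate_flgi(list(s), list(f), b, gi_table_small)
        design = DesignSpec(K=1, T=3 * b, J=3, b=b)
        reps = 20_000
        pi = flgi_probabilities(
            2,
            counts_from(list(s), list(f)),
            design,
            self.config(gi_table_small, reps=reps),
            np.random.default_rng(5),
        )
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-4) / reps)
        assert np.all(np.abs(pi - exact) < 3 * se + 1e-9)

    def test_shallow_table_is_contract_violation(self, gi_table_small, rng):
        design = DesignSpec(K=1, T=500, J=5, b=100)
        counts = counts_from([20, 1], [20, 1])
        with pytest.raises(KeyError):
            flgi_probabilities(2, counts, design, self.config(gi_table_small), rng)


class TestCFLGI:
    def config(self, table, reps=400):
        return PolicyConfig(rule="CFLGI", gi_table=table, flgi_mc_reps=reps)

    def test_control_probability_pinned(self, gi_table_small, rng):
        design = DesignSpec(K=2, T=12, J=3, b=4)
        counts = counts_from([1, 8, 1], [1, 1, 8])
        pi = cflgi_probabilities(2, counts, design, self.config(gi_table_small), rng)
        assert pi[0] == pytest.approx(1 / 3)
        assert pi.sum() == pytest.approx(1.0)

    def test_symmetric_experimental_arms(self, gi_table_small, rng):
        design = DesignSpec(K=2, T=12, J=3, b=4)
        counts = counts_from([2, 3, 3], [2, 4, 4])
        pi = cflgi_probabilities(2, counts, design, self.config(gi_table_small, reps=4000), rng)
        assert abs(pi[1] - 1 / 3) < 0.025

    def test_dominant_experimental_arm(self, gi_table_small, rng):
        design = DesignSpec(K=2, T=12, J=3, b=4)
        counts = counts_from([1, 8, 1], [1, 1, 8])
        pi = cflgi_probabilities(2, counts, design, self.config(gi_table_small), rng)
        assert pi[1] > 0.6
        assert pi[2] < 0.05

    def test_rescaled_subvector_matches_flgi_on_experimental_arms(self, gi_table_small):
        design = DesignSpec(K=2, T=12, J=3, b=4)
        counts = counts_from([2, 5, 3], [3, 2, 6])
        cfg = self.config(gi_table_small, reps=500)
        pi = cflgi_probabilities(2, counts, design, cfg, np.random.default_rng(17))
        sub = flgi_probabilities(
            2,
            counts_from([5, 3], [2, 6]),
            design,
            PolicyConfig(rule="FLGI", gi_table=gi_table_small, flgi_mc_reps=500),
            np.random.default_rng(17),
        )
        np.testing.assert_allclose(pi[1:] * 3 / 2, sub, atol=1e-12)


class TestSimplexInvariant:
    """Every rule returns a probability vector for random posterior states."""

    @pytest.mark.parametrize("rule", ["CR", "TS", "RSIHR", "FLGI", "CFLGI"])
    def test_outputs_on_simplex(self, rule, gi_table_small):
        rng = np.random.default_rng(99)
        design = DesignSpec(K=2, T=15, J=3, b=5)
        config = PolicyConfig(
            rule=rule, gi_table=gi_table_small, flgi_mc_reps=20, ts_mc_draws=200
        )
        policy = make_policy(design, config)
        for _ in range(200):
            n_obs = rng.integers(0, 6, size=3)
            succ = np.array([rng.integers(0, n + 1) for n in n_obs])
            counts = counts_from(1 + succ, 1 + n_obs - succ)
            j = int(rng.integers(1, 4))
            pi = policy.probabilities(j, counts)
            assert pi.shape == (3,)
            assert np.all(pi >= -1e-12)
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)


class TestPolicyMemoisation:
    def test_cache_is_order_independent(self, gi_table_small):
        design = DesignSpec(K=1, T=12, J=3, b=4)
        config = PolicyConfig(rule="FLGI", gi_table=gi_table_small, flgi_mc_reps=50, seed=3)
        s1 = counts_from([3, 2], [2, 4])
        s2 = counts_from([2, 4], [3, 1])
        a = make_policy(design, config)
        b = make_policy(design, config)
        pi_a1 = a.probabilities(2, s1)
        pi_b2 = b.probabilities(2, s2)
        pi_b1 = b.probabilities(2, s1)
        pi_a2 = a.probabilities(2, s2)
        np.testing.assert_array_equal(pi_a1, pi_b1)
        np.testing.assert_array_equal(pi_a2, pi_b2)
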