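"""Closed-form probability operations of the mixture tree."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

import rmmtree as rt
from rmmtree.model import InvalidParameterError, marginal_loglik_theta1

SP = rt.CategorySpace(4)
DELTA = np.array([-1.5, -0.5, 0.5, 1.5])


def random_item(rng):
    d = np.sort(rng.uniform(-2, 2, 4))
    return rng.uniform(0.2, 1.2), rng.normal(-1, 1), rng.uniform(0.3, 1.0), d


class TestCategorySpace:
    def test_middle_index(self):
        assert rt.CategorySpace(4).m == 2
        assert rt.CategorySpace(6).n_categories == 7

    @pytest.mark.parametrize("h", [3, 0, -2, 5])
    def test_odd_h_rejected(self, h):
        with pytest.raises(InvalidParameterError):
            rt.CategorySpace(h)


class TestGrmNode:
    def test_zero_thresholds_give_half(self):
        np.testing.assert_allclose(rt.grm_cumulative(0.0, 0.5, np.zeros(4)), 0.5)

    def test_zero_slope_removes_theta(self):
        d = np.array([-1.0, 0.0, 1.0, 2.0])
        for theta in (-3.0, 0.0, 4.0):
            np.testing.assert_allclose(
                rt.grm_cumulative(theta, 0.0, d), stats.norm.cdf(-d)
            )

    def test_cumulative_matches_normal_cdf(self):
        got = rt.grm_cumulative(1.0, 0.61, DELTA)
        np.testing.assert_allclose(got, stats.norm.cdf(0.61 - DELTA), rtol=1e-12)
        assert np.all(np.diff(got) <= 0)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(InvalidParameterError):
            rt.grm_cumulative(0.0, 0.5, np.array([0.0, -1.0, 1.0, 2.0]))

    def test_category_probs_are_cdf_differences(self):
        cum = stats.norm.cdf(0.61 * 1.0 - DELTA)
        expected = np.diff(np.concatenate([[1.0], cum, [0.0]])) * -1
        np.testing.assert_allclose(
            rt.grm_category_probs(1.0, 0.61, DELTA), expected, rtol=1e-12
        )

    def test_symmetric_thresholds_give_symmetric_probs(self):
        d = np.array([-2.0, -0.7, 0.7, 2.0])
        p = rt.grm_category_probs(0.0, 0.83, d)
        np.testing.assert_allclose(p, p[::-1], atol=1e-14)

    @settings(derandomize=True, max_examples=50)
    @given(
        theta=st.floats(-4, 4),
        alpha=st.floats(0, 3),
        base=st.floats(-3, 1),
        gaps=st.tuples(*[st.floats(0, 2)] * 3),
    )
    def test_probs_normalize(self, theta, alpha, base, gaps):
        d = base + np.concatenate([[0.0], np.cumsum(gaps)])
        p = rt.grm_category_probs(theta, alpha, d)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12


class TestFirstNode:
    def test_zero_slope(self):
        for theta in (-2.0, 0.0, 3.0):
            assert rt.informative_prob(theta, 0.0, 0.7) == pytest.approx(
                stats.norm.cdf(-0.7)
            )

    def test_reference_value(self):
        assert rt.informative_prob(0.0, 0.61, -1.6) == pytest.approx(
            stats.norm.cdf(1.6), abs=1e-12
        )

    def test_limits_and_monotonicity(self):
        assert rt.informative_prob(0.0, 0.61, -1000.0) == pytest.approx(1.0)
        grid = np.linspace(-4, 4, 41)
        p = rt.informative_prob(grid, 0.61, -1.0)
        assert np.all(np.diff(p) <= 0)

    def test_negative_slope_rejected(self):
        with pytest.raises(InvalidParameterError):
            rt.informative_prob(0.0, -0.1, 0.0)


class TestResponseProb:
    def test_normalizes_over_categories(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a1, b, a2, d = random_item(rng)
            t1, t2 = rng.normal(size=2)
            total = sum(
                rt.response_prob(x, t1, t2, a1, b, a2, d, SP) for x in range(5)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_informative_first_node_reduces_to_grm(self):
        g = rt.grm_category_probs(-0.3, 0.6, DELTA)
        for x in range(5):
            assert rt.response_prob(
                x, 0.5, -0.3, 0.61, -1000.0, 0.6, DELTA, SP
            ) == pytest.approx(g[x], abs=1e-12)

    def test_score_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            rt.response_prob(7, 0.0, 0.0, 0.61, -1.6, 0.6, DELTA, SP)

    def test_matches_tree_traversal_simulation(self):
        """Empirical frequencies of 10^6 simulated tree traversals."""
        t1, t2, a1, b, a2 = 0.5, -0.3, 0.61, -1.6, 0.6
        n = 10**6
        rng = np.random.default_rng(42)
        z = rng.random(n) < rt.informative_prob(t1, a1, b)
        cum = rt.grm_cumulative(t2, a2, DELTA)
        x = (rng.random(n)[:, None] < cum[None, :]).sum(axis=1)
        x[~z] = SP.m
        for cat in range(5):
            p_hat = np.mean(x == cat)
            se = np.sqrt(p_hat * (1 - p_hat) / n)
            p_model = rt.response_prob(cat, t1, t2, a1, b, a2, DELTA, SP)
            assert abs(p_model - p_hat) < 3 * se + 1e-9

    def test_upper_tail_monotone_in_theta2(self):
        """P(X >= k) for k > m is nondecreasing in the substantive trait."""
        grid = np.linspace(-3, 3, 31)
        for k in (3, 4):
            p = [
                sum(
                    rt.response_prob(c, 0.2, t, 0.61, -1.0, 0.6, DELTA, SP)
                    for c in range(k, 5)
                )
                for t in grid
            ]
            assert np.all(np.diff(p) >= -1e-12)


class TestMiddlePosterior:
    def test_always_informative_limit(self):
        assert rt.posterior_informative_given_middle(
            0.3, 0.1, 0.61, -1000.0, 0.6, DELTA, SP
        ) == pytest.approx(1.0)

    def test_slope_zero_hand_formula(self):
        """With a flat second node the posterior reduces to p*c/(1-p+p*c)."""
        d = np.array([-1.0, 0.0, 1.0, 2.0])
        c = stats.norm.cdf(0.0) - stats.norm.cdf(-1.0)  # P(X=m | Z=1), slope 0
        p = rt.informative_prob(0.4, 0.61, -0.8)
        expected = p * c / (1 - p + p * c)
        got = rt.posterior_informative_given_middle(0.4, 9.9, 0.61, -0.8, 0.0, d, SP)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_conditional_simulation(self):
        """Frequency of informative paths among simulated middle responses."""
        t1, t2, a1, b, a2 = 0.2, 0.1, 0.61, -0.5, 0.6
        n = 10**6
        rng = np.random.default_rng(7)
        z = rng.random(n) < rt.informative_prob(t1, a1, b)
        cum = rt.grm_cumulative(t2, a2, DELTA)
        x = (rng.random(n)[:, None] < cum[None, :]).sum(axis=1)
        x[~z] = SP.m
        mid = x == SP.m
        p_hat = z[mid].mean()
        se = np.sqrt(p_hat * (1 - p_hat) / mid.sum())
        got = rt.posterior_informative_given_middle(t1, t2, a1, b, a2, DELTA, SP)
        assert abs(got - p_hat) < 3 * se

    def test_mixture_decomposition_identity(self):
        """P(X=m) = P(Z=0) + P(X=m|Z=1) P(Z=1) on random draws."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            a1, b, a2, d = random_item(rng)
            t1, t2 = rng.normal(size=2)
            lhs = rt.response_prob(SP.m, t1, t2, a1, b, a2, d, SP)
            p1 = rt.informative_prob(t1, a1, b)
            rhs = (1 - p1) + rt.grm_category_probs(t2, a2, d)[SP.m] * p1
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestLogLikelihood:
    @staticmethod
    def _random_instance(rng, n, k):
        items = rt.ItemParams(
            0.61,
            rng.normal(-1, 0.3, k),
            rng.uniform(0.4, 0.8, k),
            np.sort(rng.uniform(-2, 2, (k, 4)), axis=1),
        )
        persons = rt.PersonParams(rng.normal(size=(n, 2)))
        scores = rng.integers(0, 5, (n, k))
        return rt.ResponseMatrix(scores, SP), persons, items

    def test_single_cell_nonmiddle(self):
        data = rt.ResponseMatrix(np.array([[4]]), SP)
        persons = rt.PersonParams(np.array([[0.3, 0.8]]))
        items = rt.ItemParams(0.61, [-1.2], [0.6], DELTA[None, :])
        expected = np.log(
            rt.informative_prob(0.3, 0.61, -1.2)
            * rt.grm_category_probs(0.8, 0.6, DELTA)[4]
        )
        assert rt.log_likelihood(data, persons, items) == pytest.approx(expected)

    def test_cellwise_consistency_with_response_prob(self):
        rng = np.random.default_rng(3)
        data, persons, items = self._random_instance(rng, 5, 3)
        total = sum(
            np.log(
                rt.response_prob(
                    int(data.scores[p, i]),
                    persons.theta[p, 0],
                    persons.theta[p, 1],
                    items.alpha1,
                    items.beta[i],
                    items.alpha2[i],
                    items.delta[i],
                    SP,
                )
            )
            for p in range(5)
            for i in range(3)
        )
        assert rt.log_likelihood(data, persons, items) == pytest.approx(total, abs=1e-10)

    def test_invariant_under_identification_rescaling(self):
        rng = np.random.default_rng(9)
        data, persons, items = self._random_instance(rng, 20, 6)
        mu = np.array([0.4, -0.7])
        a = rng.normal(size=(2, 2))
        Sigma = a @ a.T + np.eye(2)
        persons = rt.PersonParams(persons.theta, mu, Sigma)
        before = rt.log_likelihood(data, persons, items)
        th, mu2, S2, a1, b, a2, d = rt.rescale_identification(
            persons.theta, mu, Sigma, items.alpha1, items.beta, items.alpha2, items.delta
        )
        after = rt.log_likelihood(
            data, rt.PersonParams(th, mu2, S2), rt.ItemParams(a1, b, a2, d)
        )
        assert after == pytest.approx(before, abs=1e-10)

    def test_dimension_mismatch(self):
        rng = np.random.default_rng(1)
        data, persons, items = self._random_instance(rng, 5, 3)
        bad = rt.PersonParams(rng.normal(size=(4, 2)))
        with pytest.raises(InvalidParameterError):
            rt.log_likelihood(data, bad, items)

    def test_nesting_limits(self):
        """beta -> -inf recovers the GRM; beta -> +inf the hard tree."""
        rng = np.random.default_rng(17)
        data, persons, items = self._random_instance(rng, 15, 4)
        grm_items = rt.ItemParams(
            items.alpha1, np.full(4, -1000.0), items.alpha2, items.delta
        )
        ll_grm = sum(
            np.log(
                rt.grm_category_probs(
                    persons.theta[p, 1], items.alpha2[i], items.delta[i]
                )[data.scores[p, i]]
            )
            for p in range(15)
            for i in range(4)
        )
        assert rt.log_likelihood(data, persons, grm_items) == pytest.approx(
            ll_grm, abs=1e-8
        )
        # beta -> +inf: every response forced through the non-response path,
        # so only all-middle matrices keep positive probability
        tree_items = rt.ItemParams(
            items.alpha1, np.full(4, 1000.0), items.alpha2, items.delta
        )
        mid_data = rt.ResponseMatrix(np.full((15, 4), SP.m), SP)
        assert rt.log_likelihood(mid_data, persons, tree_items) == pytest.approx(
            0.0, abs=1e-8
        )


class TestMarginalLoglik:
    def test_constant_integrand_when_theta1_free(self):
        """Zero slope and zero correlation: integration must be exact."""
        rng = np.random.default_rng(2)
        items = rt.ItemParams(
            0.0, np.full(5, -1.2), rng.uniform(0.4, 0.8, 5),
            np.sort(rng.uniform(-2, 2, (5, 4)), axis=1),
        )
        x = rng.integers(0, 5, 5)
        got = marginal_loglik_theta1(x, 0.7, items, np.zeros(2), np.eye(2), SP)
        cond = sum(
            np.log(
                rt.response_prob(int(x[i]), 3.3, 0.7, 0.0, -1.2,
                                 items.alpha2[i], items.delta[i], SP)
            )
            for i in range(5)
        )
        assert got == pytest.approx(cond, abs=1e-10)

    def test_against_dense_grid_integration(self):
        rng = np.random.default_rng(4)
        items = rt.ItemParams(
            0.61, rng.normal(-1, 0.3, 5), rng.uniform(0.4, 0.8, 5),
            np.sort(rng.uniform(-2, 2, (5, 4)), axis=1),
        )
        x = rng.integers(0, 5, 5)
        Sigma = np.array([[1.0, -0.3], [-0.3, 1.0]])
        theta2 = 0.4

        def integrand(t1):
            val = 1.0
            for i in range(5):
                val *= rt.response_prob(
                    int(x[i]), t1, theta2, items.alpha1, items.beta[i],
                    items.alpha2[i], items.delta[i], SP,
                )
            c, s2 = -0.3 * theta2, 1 - 0.3**2
            return val * np.exp(-0.5 * (t1 - c) ** 2 / s2) / np.sqrt(2 * np.pi * s2)

        oracle = np.log(quad(integrand, -9, 9, limit=200)[0])
        got = marginal_loglik_theta1(x, theta2, items, np.zeros(2), Sigma, SP)
        assert got == pytest.approx(oracle, abs=1e-4)
        got40 = marginal_loglik_theta1(
            x, theta2, items, np.zeros(2), Sigma, SP, n_nodes=40
        )
        assert abs(got40 - got) < 1e-3

    def test_non_pd_sigma_rejected(self):
        items = rt.ItemParams(0.61, [-1.0], [0.6], DELTA[None, :])
        with pytest.raises(InvalidParameterError):
            marginal_loglik_theta1(
                np.array([2]), 0.0, items, np.zeros(2),
                np.array([[1.0, 2.0], [2.0, 1.0]]), SP,
            )
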