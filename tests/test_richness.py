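"""Occupancy-model distribution, MLE and profile-CI tests.

The pmf is checked against two independent oracles: exact rational
enumeration of all theta^n equally likely draw sequences (small cases) and
the independently coded Stirling closed form (larger cases).
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bacrichness.richness import (
    ObservedRichness,
    estimate_richness,
    expected_distinct,
    log_likelihood,
    log_stirling2,
    mle_theta,
    occupancy_pmf,
    occupancy_pmf_closed,
    profile_ci,
)


def enumerate_distinct_pmf(n: int, theta: int) -> dict[int, Fraction]:
    """Brute-force oracle: exact P(K_n = k) by enumerating all theta^n sequences."""
    counts: dict[int, int] = {}
    for seq in itertools.product(range(theta), repeat=n):
        k = len(set(seq))
        counts[k] = counts.get(k, 0) + 1
    total = theta**n
    return {k: Fraction(c, total) for k, c in counts.items()}


class TestOccupancyPMF:
    @pytest.mark.parametrize(
        "n, theta, expected",
        [
            (2, 2, {1: 0.5, 2: 0.5}),
            (3, 2, {1: 0.25, 2: 0.75}),
            (3, 3, {1: 1 / 9, 2: 2 / 3, 3: 2 / 9}),
        ],
    )
    def test_small_cases(self, n, theta, expected):
        pmf = occupancy_pmf(n, theta)
        for k, p in expected.items():
            assert pmf.prob(k) == pytest.approx(p, abs=1e-12)

    def test_matches_exact_enumeration(self):
        """Recursion agrees with exhaustive enumeration of all draw sequences."""
        for n in range(1, 7):
            for theta in range(1, 7):
                oracle = enumerate_distinct_pmf(n, theta)
                pmf = occupancy_pmf(n, theta)
                for k in range(1, min(n, theta) + 1):
                    assert pmf.prob(k) == pytest.approx(float(oracle.get(k, 0)), abs=1e-12)

    def test_matches_closed_form(self):
        """Recursion and Stirling closed form agree to 1e-10 over n, theta <= 25."""
        for n in range(1, 26):
            for theta in range(1, 26):
                pmf = occupancy_pmf(n, theta)
                for k in range(1, min(n, theta) + 1):
                    assert abs(pmf.prob(k) - occupancy_pmf_closed(n, k, theta)) < 1e-10

    def test_normalization(self):
        for n in range(1, 31):
            for theta in (1, 2, 5, 13, 30):
                assert abs(occupancy_pmf(n, theta).probs.sum() - 1.0) <= 1e-12

    def test_mean_equals_closed_form_expectation(self):
        for n, theta in [(10, 7), (50, 50), (100, 40), (100, 100), (77, 3)]:
            pmf = occupancy_pmf(n, theta)
            assert pmf.mean() == pytest.approx(expected_distinct(theta, n), abs=1e-9)

    def test_out_of_support_zero(self):
        pmf = occupancy_pmf(4, 3)
        assert pmf.prob(0) == 0.0
        assert pmf.prob(4) == 0.0
        assert occupancy_pmf_closed(4, 4, 3) == 0.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            occupancy_pmf(0, 5)
        with pytest.raises(ValueError):
            occupancy_pmf(5, 0)

    def test_monte_carlo_total_variation(self):
        """Empirical distribution of 1e5 simulated screens is TV-close to the pmf."""
        rng = np.random.default_rng(20090417)
        n, theta, reps = 20, 10, 100_000
        draws = rng.integers(0, theta, size=(reps, n))
        distinct = (np.sort(draws, axis=1)[:, 1:] != np.sort(draws, axis=1)[:, :-1]).sum(axis=1) + 1
        emp = np.bincount(distinct, minlength=theta + 1)[1 : theta + 1] / reps
        tv = 0.5 * np.abs(emp - occupancy_pmf(n, theta).probs).sum()
        assert tv < 0.01


class TestClosedForm:
    @pytest.mark.parametrize(
        "n, k, theta, expected",
        [
            (3, 3, 3, 6 / 27),          # all distinct: theta!/theta^n
            (4, 1, 5, 5.0 ** (-3)),      # all identical: theta^(1-n)
            (5, 3, 3, 150 / 243),        # S2(5,3)=25
        ],
    )
    def test_known_values(self, n, k, theta, expected):
        assert occupancy_pmf_closed(n, k, theta) == pytest.approx(expected, rel=1e-12)

    def test_stirling_row_known_values(self):
        # S2(5,k) = 1, 15, 25, 10, 1
        for k, s2 in [(1, 1), (2, 15), (3, 25), (4, 10), (5, 1)]:
            assert math.exp(log_stirling2(5, k)) == pytest.approx(s2, rel=1e-12)

    def test_large_n_finite(self):
        """The N=342 likelihood row stays finite in log space."""
        val = log_likelihood(1240, ObservedRichness(342, 299))
        assert np.isfinite(val) and val < 0


class TestLikelihoodAndMLE:
    def test_loglik_product_form_at_saturation(self):
        # theta = K = N: every draw distinct, P = theta!/theta^n
        obs = ObservedRichness(3, 3)
        assert log_likelihood(3, obs) == pytest.approx(math.log(2 / 9), abs=1e-12)

    def test_impossible_observation_is_neg_inf(self):
        assert log_likelihood(5, ObservedRichness(10, 8)) == -np.inf

    def test_mle_local_maximum_at_published_obs(self):
        obs = ObservedRichness(342, 299)
        l0 = log_likelihood(1240, obs)
        assert l0 > log_likelihood(1239, obs)
        assert l0 > log_likelihood(1241, obs)

    def test_mle_small_case_by_exhaustive_scan(self):
        """N=5, K=3: exhaustive scan over theta confirms the walk-up result."""
        obs = ObservedRichness(5, 3)
        scan = {t: log_likelihood(t, obs) for t in range(3, 51)}
        best = min([t for t, v in scan.items() if v == max(scan.values())])
        theta_hat, unbounded = mle_theta(obs)
        assert not unbounded and theta_hat == best == 3

    def test_mle_single_class(self):
        theta_hat, unbounded = mle_theta(ObservedRichness(10, 1))
        assert theta_hat == 1 and not unbounded

    def test_mle_unbounded_when_all_distinct(self):
        theta_hat, unbounded = mle_theta(ObservedRichness(7, 7))
        assert unbounded and theta_hat is None

    def test_likelihood_ratio_crosses_one_once(self):
        """Unimodality: L(theta+1)/L(theta) decreasing through 1 at most once."""
        obs = ObservedRichness(100, 80)
        ratios = [log_likelihood(t + 1, obs) - log_likelihood(t, obs) for t in range(80, 2000)]
        signs = [r > 0 for r in ratios]
        assert sorted(signs, reverse=True) == signs  # True...False, one crossing


class TestProfileCI:
    def test_degenerate_alpha_collapses_to_mle(self):
        obs = ObservedRichness(342, 299)
        lo, hi = profile_ci(obs, alpha=1 - 1e-12)
        assert lo == hi == 1240

    def test_nesting_of_levels(self):
        obs = ObservedRichness(342, 299)
        lo95, hi95 = profile_ci(obs, alpha=0.05)
        lo90, hi90 = profile_ci(obs, alpha=0.10)
        assert lo95 < lo90 and hi90 < hi95

    def test_unbounded_upper(self):
        lo, hi = profile_ci(ObservedRichness(4, 4), alpha=0.05)
        assert lo == 4 and hi is None

    def test_estimate_wrapper_consistency(self):
        obs = ObservedRichness(120, 90)
        est = estimate_richness(obs, alpha=0.05)
        assert est.ci_low <= est.theta_hat <= est.ci_high
        assert est.theta_hat >= obs.k
        # profile grid covers the CI and is unimodal
        assert est.profile_theta[0] == obs.k and est.profile_theta[-1] > est.ci_high
        diffs = np.sign(np.diff(est.profile_loglik))
        assert np.all(np.diff(np.where(diffs < 0, 0, 1)) <= 0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            profile_ci(ObservedRichness(10, 5), alpha=1.5)


class TestExpectedDistinct:
    @given(theta=st.integers(1, 100), n=st.integers(1, 100))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pmf_mean(self, theta, n):
        assert occupancy_pmf(n, theta).mean() == pytest.approx(
            expected_distinct(theta, n), abs=1e-9
        )

    def test_first_draw_always_new(self):
        for theta in (1, 5, 1000):
            assert expected_distinct(theta, 1) == pytest.approx(1.0)

    def test_two_draws_two_classes(self):
        assert expected_distinct(2, 2) == pytest.approx(1.5)


class TestObservedRichness:
    def test_validation(self):
        with pytest.raises(ValueError):
            ObservedRichness(5, 6)
        with pytest.raises(ValueError):
            ObservedRichness(5, 0)
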