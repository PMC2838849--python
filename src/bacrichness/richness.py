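"""Occupancy-model richness estimation.

The model: ``n`` clones are sampled independently and uniformly (with
replacement) from ``theta`` equally abundant genotype classes.  The number of
distinct classes observed, ``K_n``, follows the classical occupancy law

    P(K_n = k | theta) = S2(n, k) * theta * (theta-1) * ... * (theta-k+1) / theta^n

with ``S2`` the Stirling number of the second kind.  The same law is available
through the one-step recursion

    P(K_{i+1} = k) = P(K_i = k) * k/theta + P(K_i = k-1) * (theta-k+1)/theta

starting from ``P(K_1 = 1) = 1``.  Both routes are implemented (the recursion
as the primary path, the closed form as an independently-coded twin used to
cross-check it) and all arithmetic is carried in log space so that the
``n = 342`` likelihood evaluations the estimator needs never underflow.

Given an observed pair ``(N, K)`` the total class count ``theta`` is estimated
by maximising the likelihood over integers ``theta >= K``, and a profile
confidence interval is formed from the chi-square(1) cutoff:
``{theta : 2 * (loglik(theta_hat) - loglik(theta)) <= chi2_{1, 1-alpha}}``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "ObservedRichness",
    "OccupancyPMF",
    "RichnessEstimate",
    "occupancy_pmf",
    "occupancy_pmf_closed",
    "log_stirling2",
    "log_likelihood",
    "mle_theta",
    "profile_ci",
    "expected_distinct",
    "estimate_richness",
]


@dataclass(frozen=True)
class ObservedRichness:
    """Sufficient statistic of the occupancy model: N draws, K distinct."""

    n: int
    k: int

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and isinstance(self.k, (int, np.integer))):
            raise TypeError("n and k must be integers")
        if not 1 <= self.k <= self.n:
            raise ValueError(f"require 1 <= K <= N, got N={self.n}, K={self.k}")


@dataclass(frozen=True)
class OccupancyPMF:
    """P(K_n = k | theta) over the support k = 1..min(n, theta)."""

    n: int
    theta: int
    log_probs: np.ndarray  # index k-1 -> log P(K_n = k)

    @property
    def support(self) -> np.ndarray:
        return np.arange(1, min(self.n, self.theta) + 1)

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    def prob(self, k: int) -> float:
        if 1 <= k <= min(self.n, self.theta):
            return float(np.exp(self.log_probs[k - 1]))
        return 0.0

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs))


@dataclass(frozen=True)
class RichnessEstimate:
    """Integer MLE of the class count with a profile-likelihood CI."""

    observed: ObservedRichness
    theta_hat: int | None
    ci_low: int | None
    ci_high: int | None
    alpha: float
    unbounded: bool
    profile_theta: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    profile_loglik: np.ndarray = field(default_factory=lambda: np.array([]))


def _validate_counts(n: int, theta: int) -> None:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")


def occupancy_pmf(n: int, theta: int) -> OccupancyPMF:
    """Distribution of the number of distinct classes in ``n`` uniform draws.

    Forward recursion over draws, in log space: at each step a draw repeats an
    already-seen class with probability ``k/theta`` or reveals a new one with
    probability ``(theta - k)/theta``.
    """
    _validate_counts(n, theta)
    kmax = min(n, theta)
    log_theta = math.log(theta)
    # log P(K_i = k) at index k-1; start at i = 1
    cur = np.full(kmax, -np.inf)
    cur[0] = 0.0
    for _ in range(1, n):
        nxt = np.full(kmax, -np.inf)
        ks = np.arange(1, kmax + 1)
        stay = cur + np.log(ks) - log_theta  # repeat one of the k seen classes
        nxt = stay
        if kmax > 1:
            new = cur[:-1] + np.log(theta - ks[1:] + 1) - log_theta
            nxt = np.concatenate(([stay[0]], np.logaddexp(stay[1:], new)))
        cur = nxt
    return OccupancyPMF(n=n, theta=theta, log_probs=cur)


@lru_cache(maxsize=8)
def _log_stirling2_row(n: int) -> np.ndarray:
    """log S2(n, k) for k = 0..n via the triangular recurrence.

    S2(n, k) = k * S2(n-1, k) + S2(n-1, k-1), combined with log-sum-exp so the
    n = 342 row (values up to ~10^700) stays finite.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # S2(0, 0) = 1
    for m in range(1, n + 1):
        nxt = np.full(n + 1, -np.inf)
        ks = np.arange(1, m + 1)
        nxt[1 : m + 1] = np.logaddexp(np.log(ks) + row[1 : m + 1], row[0:m])
        row = nxt
    return row


def log_stirling2(n: int, k: int) -> float:
    """log of the Stirling number of the second kind S2(n, k)."""
    if not 0 <= k <= n:
        return -np.inf
    return float(_log_stirling2_row(n)[k])


def occupancy_pmf_closed(n: int, k: int, theta: int) -> float:
    """Closed-form P(K_n = k | theta): S2(n,k) * theta falling-factorial k / theta^n.

    Independent of :func:`occupancy_pmf`; used as its cross-check oracle.
    """
    _validate_counts(n, theta)
    if not 1 <= k <= min(n, theta):
        return 0.0
    log_ff = gammaln(theta + 1) - gammaln(theta - k + 1)
    return float(math.exp(log_stirling2(n, k) + log_ff - n * math.log(theta)))


def log_likelihood(theta: int, obs: ObservedRichness) -> float:
    """log P(K_N = K | theta); ``-inf`` when theta < K (impossible observation)."""
    if theta < 1:
        raise ValueError(f"theta must be >= 1, got {theta}")
    if theta < obs.k:
        return -np.inf
    log_ff = float(gammaln(theta + 1) - gammaln(theta - obs.k + 1))
    return log_stirling2(obs.n, obs.k) + log_ff - obs.n * math.log(theta)


def _log_lik_ratio(theta: int, obs: ObservedRichness) -> float:
    """log L(theta + 1) - log L(theta), finite for theta >= K."""
    n, k = obs.n, obs.k
    return math.log((theta + 1) / (theta + 1 - k)) - n * math.log((theta + 1) / theta)


def mle_theta(obs: ObservedRichness, theta_max: int | None = None) -> tuple[int | None, bool]:
    """Smallest integer theta maximising the likelihood; ``(None, True)`` if unbounded.

    When K = N every draw was distinct and the likelihood increases in theta
    without bound, so no point estimate exists.  Otherwise the likelihood
    ratio L(theta+1)/L(theta) decreases through 1 exactly once and the walk
    upward from theta = K stops at the maximum.
    """
    if obs.k == obs.n:
        return None, True
    theta = obs.k
    cap = theta_max if theta_max is not None else None
    while _log_lik_ratio(theta, obs) > 0:
        theta += 1
        if cap is not None and theta >= cap:
            break
    return theta, False


def profile_ci(obs: ObservedRichness, alpha: float = 0.05) -> tuple[int, int | None]:
    """Extreme integers theta with 2*(loglik(theta_hat) - loglik(theta)) <= chi2_1(1-alpha).

    Scans outward from the MLE; endpoints are integers, no interpolation.
    The upper bound is ``None`` (unbounded) when K = N.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    theta_hat, unbounded = mle_theta(obs)
    if unbounded:
        return obs.k, None
    cutoff = chi2.ppf(1 - alpha, df=1) / 2.0
    lmax = log_likelihood(theta_hat, obs)
    lo = theta_hat
    while lo > obs.k and lmax - log_likelihood(lo - 1, obs) <= cutoff:
        lo -= 1
    hi = theta_hat
    while lmax - log_likelihood(hi + 1, obs) <= cutoff:
        hi += 1
    return lo, hi


def expected_distinct(theta: int, n: int) -> float:
    """Expected number of distinct classes: theta * (1 - (1 - 1/theta)^n)."""
    _validate_counts(n, theta)
    if theta == 1:
        return 1.0
    return theta * (1.0 - (1.0 - 1.0 / theta) ** n)


def estimate_richness(obs: ObservedRichness, alpha: float = 0.05) -> RichnessEstimate:
    """MLE + profile CI + log-likelihood profile over the searched theta grid.

    The profile grid runs from K up past the point where the log-likelihood
    has fallen 10 units below the maximum, so the CI can never be silently
    truncated by the grid.
    """
    theta_hat, unbounded = mle_theta(obs)
    if unbounded:
        return RichnessEstimate(
            observed=obs, theta_hat=None, ci_low=obs.k, ci_high=None,
            alpha=alpha, unbounded=True,
        )
    ci_low, ci_high = profile_ci(obs, alpha=alpha)
    lmax = log_likelihood(theta_hat, obs)
    hi = ci_high
    while lmax - log_likelihood(hi, obs) < 10.0:
        hi = max(hi + 1, int(hi * 1.05))
    grid = np.arange(obs.k, hi + 1)
    prof = np.array([log_likelihood(int(t), obs) for t in grid])
    return RichnessEstimate(
        observed=obs, theta_hat=theta_hat, ci_low=ci_low, ci_high=ci_high,
        alpha=alpha, unbounded=False, profile_theta=grid, profile_loglik=prof,
    )
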