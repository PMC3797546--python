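"""Model-free controller: a table of Beta posteriors over action values.

Non-terminal updates bootstrap the successor's best-action distribution onto a
cost-adjusted, discounted target mean, reshape it (variance-increasing), and
fold it into the entry with the moment-matched mixture rule.  Terminal updates
are fractional Bernoulli observations of the received payout.
"""

from __future__ import annotations

import numpy as np

from .bayes_core import (
    BetaDist,
    clamp_mean,
    decay_toward_prior,
    mixture_moments,
    beta_from_moments,
    _reshape_params,
    PARAM_FLOOR,
)

__all__ = ["CacheQTable", "td_target_mean", "best_and_second", "cache_update"]


class CacheQTable:
    """(state, action) -> Beta posterior over the cached Q-value.

    Array-backed for speed; entries start at (and decay back toward) their
    stored priors.
    """

    def __init__(self, n_states: int, n_actions: int, prior: BetaDist = BetaDist(1.0, 1.0)):
        self.n_states = int(n_states)
        self.n_actions = int(n_actions)
        self.alpha = np.full((n_states, n_actions), prior.alpha, dtype=float)
        self.beta = np.full((n_states, n_actions), prior.beta, dtype=float)
        self.prior_alpha = self.alpha.copy()
        self.prior_beta = self.beta.copy()

    def _check(self, state: int, action: int) -> None:
        if not (0 <= state < self.n_states and 0 <= action < self.n_actions):
            raise KeyError(f"unknown (state, action) = ({state}, {action})")

    def dist(self, state: int, action: int) -> BetaDist:
        self._check(state, action)
        return BetaDist(self.alpha[state, action], self.beta[state, action])

    def set_dist(self, state: int, action: int, d: BetaDist) -> None:
        self._check(state, action)
        self.alpha[state, action] = d.alpha
        self.beta[state, action] = d.beta

    def mean(self, state: int, action: int) -> float:
        self._check(state, action)
        a = self.alpha[state, action]
        return a / (a + self.beta[state, action])

    def means(self, state: int) -> np.ndarray:
        a = self.alpha[state]
        return a / (a + self.beta[state])

    def decay(self, theta: float) -> None:
        """One forgetting step toward the priors, applied to every entry.

        In-place equivalent of :func:`~dualsys.bayes_core.decay_toward_prior`.
        """
        if not (0.0 <= theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1], got {theta!r}")
        one_m = 1.0 - theta
        self.alpha *= theta
        self.alpha += one_m * self.prior_alpha
        self.beta *= theta
        self.beta += one_m * self.prior_beta


def td_target_mean(successor_best_mean: float, action_reward: float, gamma: float) -> float:
    """Discounted, cost-adjusted bootstrap target, clamped into (0, 1)."""
    return clamp_mean(gamma * successor_best_mean + action_reward)


def best_and_second(table: CacheQTable, state: int) -> tuple[int, int]:
    """Actions with highest and second-highest posterior mean.

    Ties resolve by the fixed action ordering (lower index wins), keeping runs
    reproducible.
    """
    if table.n_actions < 2:
        raise ValueError("state must offer at least two actions")
    means = table.means(state)
    order = np.argsort(-means, kind="stable")
    return int(order[0]), int(order[1])


def cache_update(
    table: CacheQTable,
    state: int,
    action: int,
    *,
    successor_best: BetaDist | None = None,
    terminal_reward: float | None = None,
    action_reward: float = 0.0,
    gamma: float = 1.0,
) -> CacheQTable:
    """Update one cache entry after executing (state, action).

    Exactly one of ``successor_best`` (non-terminal bootstrap) or
    ``terminal_reward`` (observed terminal payout) must be supplied.
    """
    table._check(state, action)
    if (successor_best is None) == (terminal_reward is None):
        raise ValueError("provide exactly one of successor_best / terminal_reward")

    if terminal_reward is not None:
        # Fractional Bernoulli observation of the clamped payout.
        x = min(max(terminal_reward + action_reward, 0.0), 1.0)
        table.alpha[state, action] += x
        table.beta[state, action] += 1.0 - x
        return table

    sb_a, sb_b = successor_best.alpha, successor_best.beta
    mu_hat = td_target_mean(sb_a / (sb_a + sb_b), action_reward, gamma)
    qa, qb = _reshape_params(sb_a, sb_b, mu_hat)
    # target moments of the reshaped Beta(qa, qb)
    s = qa + qb
    t_mean = qa / s
    t_m2 = qa * (qa + 1.0) / (s * (s + 1.0))
    mean, var = mixture_moments(table.alpha[state, action], table.beta[state, action], t_mean, t_m2)
    d = beta_from_moments(mean, var)
    table.alpha[state, action] = d.alpha
    table.beta[state, action] = d.beta
    return table
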