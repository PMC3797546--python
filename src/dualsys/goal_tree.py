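"""Model-based controller: learned world model plus value iteration.

The world model keeps a Dirichlet row over successors per (state, action) and
a Beta reward posterior per rewarding state.  Mean shifts of the transition
rows caused by observations are the learning-progress signal that generates
intrinsic reward; planning is synchronous value iteration to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .bayes_core import BetaDist, DirichletRow, decay_toward_prior

try:  # optional fast path; the numpy implementation below is authoritative
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

__all__ = [
    "WorldModel",
    "TreeQ",
    "observe_transition",
    "intrinsic_reward",
    "update_reward",
    "value_iteration",
    "augmented_q",
    "devalue_state",
]


@dataclass
class TreeQ:
    """Result of one tree-search: mean Q-values plus convergence diagnostics."""

    values: np.ndarray  # (n_states, n_actions)
    converged: bool
    sweeps_used: int


class WorldModel:
    """Dirichlet transition model + Beta reward model over observed states.

    ``reward_states`` marks states carrying an extrinsic reward posterior
    (images of terminal states); ``terminal_states`` is the subset whose every
    underlying state ends the episode.  States that are rewarding but not
    fully terminal can be passed through, so planning values them at the
    larger of their reward estimate and their continuation value.
    """

    def __init__(
        self,
        n_states: int,
        n_actions: int,
        transition_prior: float = 0.1,
        reward_states: Iterable[int] = (),
        terminal_states: Iterable[int] = (),
        reward_prior: BetaDist = BetaDist(1.0, 1.0),
        reward_active: bool = False,
    ):
        if transition_prior <= 0:
            raise ValueError("transition_prior must be positive")
        self.n_states = int(n_states)
        self.n_actions = int(n_actions)
        self.trans = np.full((n_states, n_actions, n_states), float(transition_prior))
        self.trans_prior = self.trans.copy()
        self.reward_mask = np.zeros(n_states, dtype=bool)
        self.reward_mask[list(reward_states)] = True
        self.terminal_mask = np.zeros(n_states, dtype=bool)
        self.terminal_mask[list(terminal_states)] = True
        if np.any(self.terminal_mask & ~self.reward_mask):
            raise ValueError("every terminal state needs a reward entry")
        self.reward_alpha = np.full(n_states, reward_prior.alpha)
        self.reward_beta = np.full(n_states, reward_prior.beta)
        self.reward_prior_alpha = self.reward_alpha.copy()
        self.reward_prior_beta = self.reward_beta.copy()
        # reward entries activate on first observation (or devaluation)
        # unless reward_active pre-arms them; an inactive entry promises
        # nothing to the planner
        self.reward_seen = self.reward_mask.copy() if reward_active else np.zeros(n_states, dtype=bool)
        self.last_shift = np.zeros((n_states, n_actions))
        # row sums tracked incrementally; planning normalizes against these
        self._rowsum = self.trans.sum(axis=-1)
        self._prior_rowsum = self.trans_prior.sum(axis=-1)

    # -- accessors ---------------------------------------------------------
    def _check(self, state: int, action: int | None = None) -> None:
        if not 0 <= state < self.n_states:
            raise KeyError(f"unknown state {state}")
        if action is not None and not 0 <= action < self.n_actions:
            raise KeyError(f"unknown action {action}")

    def transition_row(self, state: int, action: int) -> DirichletRow:
        self._check(state, action)
        return DirichletRow(self.trans[state, action].copy())

    def reward_dist(self, state: int) -> BetaDist:
        self._check(state)
        if not self.reward_mask[state]:
            raise KeyError(f"state {state} has no reward entry")
        return BetaDist(self.reward_alpha[state], self.reward_beta[state])

    def reward_means(self) -> np.ndarray:
        """Posterior mean payout per state; zero until a state has been seen."""
        out = np.zeros(self.n_states)
        m = self.reward_mask & self.reward_seen
        out[m] = self.reward_alpha[m] / (self.reward_alpha[m] + self.reward_beta[m])
        return out

    def decay(self, theta: float) -> None:
        """One forgetting step for every transition and reward parameter.

        Decay-induced drift is deliberately not counted toward ``last_shift``:
        it is homogeneous over the whole table and carries no information.
        In-place equivalent of :func:`~dualsys.bayes_core.decay_toward_prior`.
        """
        if not (0.0 <= theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1], got {theta!r}")
        one_m = 1.0 - theta
        self.trans *= theta
        self.trans += one_m * self.trans_prior
        self._rowsum *= theta
        self._rowsum += one_m * self._prior_rowsum
        self.reward_alpha *= theta
        self.reward_alpha += one_m * self.reward_prior_alpha
        self.reward_beta *= theta
        self.reward_beta += one_m * self.reward_prior_beta


def observe_transition(model: WorldModel, state: int, action: int, successor: int):
    """Record one observed transition; returns (model, mean-shift magnitude).

    The shift is the L1 change of the Dirichlet row mean and is stored as the
    pair's most recent learning progress.
    """
    model._check(state, action)
    model._check(successor)
    row = model.trans[state, action]
    rs = model._rowsum[state, action]
    before = row / rs
    row[successor] += 1.0
    model._rowsum[state, action] = rs + 1.0
    after = row / (rs + 1.0)
    shift = float(np.abs(after - before).sum())
    model.last_shift[state, action] = shift
    return model, shift


def intrinsic_reward(model: WorldModel, state: int, action: int, iota: float) -> float:
    """Learning-progress reward: iota times the most recent mean shift."""
    model._check(state, action)
    return float(iota * model.last_shift[state, action])


def update_reward(model: WorldModel, state: int, r: float) -> WorldModel:
    """Bernoulli-style update of a state's extrinsic reward posterior."""
    if not model.reward_mask[state]:
        raise KeyError(f"state {state} has no reward entry")
    x = min(max(float(r), 0.0), 1.0)
    model.reward_seen[state] = True
    model.reward_alpha[state] += x
    model.reward_beta[state] += 1.0 - x
    return model


def devalue_state(model: WorldModel, state: int, new_reward: BetaDist) -> WorldModel:
    """Replace a reward entry *and its prior*, so forgetting cannot undo it."""
    if not model.reward_mask[state]:
        raise KeyError(f"state {state} has no reward entry")
    model.reward_seen[state] = True
    model.reward_alpha[state] = new_reward.alpha
    model.reward_beta[state] = new_reward.beta
    model.reward_prior_alpha[state] = new_reward.alpha
    model.reward_prior_beta[state] = new_reward.beta
    return model


def value_iteration(
    model: WorldModel,
    gamma: float,
    action_rewards: np.ndarray,
    scope: str = "local",
    iota: float = 0.0,
    tol: float = 1e-4,
    max_sweeps: int = 1000,
    q_init: np.ndarray | None = None,
) -> TreeQ:
    """Synchronous value iteration on the learned model's mean dynamics.

    Backup: Q(s,a) <- sum_s' P(s'|s,a) [r_a + gamma V(s')], with V equal to
    the reward-model mean at terminal states and max_a Q elsewhere; states
    that are rewarding but not fully terminal take the larger of the two.
    With ``scope="global"`` the per-pair intrinsic reward is injected into
    every backup alongside r_a.
    """
    if scope not in ("local", "global"):
        raise ValueError(f"scope must be 'local' or 'global', got {scope!r}")
    S, A = model.n_states, model.n_actions
    rmean = model.reward_means()
    ar = np.asarray(action_rewards, dtype=float)
    base = ar if ar.shape == (S, A) else np.broadcast_to(ar, (S, A))
    if scope == "global" and iota != 0.0:
        base = base + iota * model.last_shift
    terminal = model.terminal_mask
    passthru = model.reward_mask & ~terminal

    if q_init is not None:
        Q = np.array(q_init, dtype=float, copy=True)
        if Q.shape != (S, A):
            raise ValueError("q_init shape mismatch")
    else:
        Q = np.repeat(rmean[:, None], A, axis=1)  # initialized to the reward function
    any_terminal = bool(terminal.any())
    if any_terminal:
        Q[terminal] = 0.0

    if _numba is not None:
        sweeps, conv = _vi_sweeps_jit(
            model.trans, model._rowsum, np.ascontiguousarray(base), rmean,
            terminal, passthru, float(gamma), float(tol), int(max_sweeps), Q,
        )
        return TreeQ(values=Q, converged=bool(conv), sweeps_used=int(sweeps))

    # pure-numpy fallback, identical backup
    Pm = (model.trans / model._rowsum[..., None]).reshape(S * A, S)
    any_passthru = bool(passthru.any())
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        V = Q.max(axis=1)
        if any_passthru:
            np.maximum(V, rmean, out=V, where=passthru)
        if any_terminal:
            V[terminal] = rmean[terminal]
        Qn = (Pm @ V).reshape(S, A)
        Qn *= gamma
        Qn += base
        if any_terminal:
            Qn[terminal] = 0.0
        resid = float(np.max(np.abs(Qn - Q)))
        Q = Qn
        if resid <= tol:
            converged = True
            break
    return TreeQ(values=Q, converged=converged, sweeps_used=sweeps)


def _vi_sweeps_impl(trans, rowsum, base, rmean, terminal, passthru, gamma, tol, max_sweeps, Q):
    """Sweep loop shared by the jitted and interpreted paths; mutates Q."""
    S, A = Q.shape
    V = np.empty(S)
    sweeps = 0
    converged = False
    for sweeps in range(1, max_sweeps + 1):
        for s in range(S):
            if terminal[s]:
                V[s] = rmean[s]
            else:
                m = Q[s, 0]
                for a in range(1, A):
                    if Q[s, a] > m:
                        m = Q[s, a]
                if passthru[s] and rmean[s] > m:
                    m = rmean[s]
                V[s] = m
        resid = 0.0
        for s in range(S):
            if terminal[s]:
                continue
            for a in range(A):
                acc = 0.0
                row = trans[s, a]
                for s2 in range(S):
                    acc += row[s2] * V[s2]
                q = base[s, a] + gamma * acc / rowsum[s, a]
                d = q - Q[s, a]
                if d < 0.0:
                    d = -d
                if d > resid:
                    resid = d
                Q[s, a] = q
        if resid <= tol:
            converged = True
            break
    return sweeps, converged


if _numba is not None:
    _vi_sweeps_jit = _numba.njit(cache=False, fastmath=False)(_vi_sweeps_impl)


def augmented_q(
    tree: TreeQ, model: WorldModel, state: int, iota: float, scope: str = "local"
) -> np.ndarray:
    """Per-action tree values for one state, with local intrinsic bonus.

    Under global scope the intrinsic reward is already inside the backups, so
    the tree values pass through unchanged.
    """
    model._check(state)
    q = tree.values[state].copy()
    if scope == "local" and iota != 0.0:
        q += iota * model.last_shift[state]
    return q
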