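"""The decision loop tying both controllers, arbitration and the environment.

One cycle = one environment step: per-action system selection, a single tree
search if any action calls for it, epsilon-greedy choice over the mixed
Q-values, then model observation, cache update, reward-model update, average-
reward update and parameter forgetting, in that fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .arbitration import ArbitrationState, update_avg_reward, vpi_values
from .bayes_core import BetaDist
from .environments import Devaluation, Environment, MDPSpec, obs_states_for_devaluation
from .goal_tree import (
    WorldModel,
    augmented_q,
    devalue_state,
    observe_transition,
    update_reward,
    value_iteration,
)
from .habitual_cache import CacheQTable, cache_update

__all__ = ["AgentConfig", "StepRecord", "Agent", "act", "decide", "records_to_dataframe", "write_trace"]


@dataclass
class AgentConfig:
    """All run parameters; defaults are the Playroom set."""

    epsilon: float = 0.2
    gamma: float = 0.95
    theta: float = 0.9999
    iota: float = 2.0
    tau: float = 0.1
    eta: float = 0.001
    transition_prior: float = 0.1
    cache_prior: tuple = (1.0, 1.0)
    reward_prior: tuple = (1.0, 1.0)
    # pre-arm reward entries with their priors (small tasks whose terminals
    # are met within the first episodes); lazily activated otherwise
    reward_prior_active: bool = False
    intrinsic_enabled: bool = True
    scope: str = "local"  # "local" | "global"
    reward_mode: str = "observed"  # "observed" | "fixed"
    fixed_avg_reward: float = 1.0
    vi_tol: float = 1e-4
    vi_max_sweeps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError("theta must lie in [0, 1]")
        if self.scope not in ("local", "global"):
            raise ValueError("scope must be 'local' or 'global'")

    @classmethod
    def playroom_defaults(cls, **overrides) -> "AgentConfig":
        return cls(**overrides)

    @classmethod
    def feeder_defaults(cls, **overrides) -> "AgentConfig":
        # The feeder is undiscounted and forgets faster; the stronger
        # forgetting keeps a persistent VPI floor so habituation is driven by
        # the rising opportunity cost rather than posterior collapse.  Action
        # rewards live in the task spec (all zero there), not here.
        base = dict(gamma=1.0, theta=0.92, eta=0.0005, reward_prior_active=True)
        base.update(overrides)
        return cls(**base)


class StepRecord(NamedTuple):
    """One logged decision cycle."""

    episode: int
    step: int
    obs_state: int
    greedy_action: int
    executed_action: int
    systems: tuple  # per action: "tree" | "cache"
    searched: bool
    tree_search_count: int
    extrinsic_reward: float
    intrinsic_reward: float
    avg_reward: float


class EpisodeSummary(NamedTuple):
    episode: int
    n_steps: int
    terminal_true_state: int | None  # None if truncated at the step cap
    extrinsic_reward: float


def records_to_dataframe(records: list[StepRecord]) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=StepRecord._fields)
    df["systems"] = df["systems"].map(lambda t: "|".join(t))
    return df


def write_trace(records: list[StepRecord], path, config: "AgentConfig") -> None:
    """Write a per-step trace CSV with a run-metadata JSON alongside."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_dataframe(records).to_csv(path, index=False)
    meta = {"config": asdict(config), "seed": config.seed, "code_version": __version__}
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def decide(
    state: int,
    cache: CacheQTable,
    model: WorldModel,
    arb: ArbitrationState,
    config: AgentConfig,
    action_rewards: np.ndarray,
    q_init: np.ndarray | None = None,
):
    """Per-action arbitration followed by at most one tree search.

    Returns (q_star, systems, searched, tree) where ``tree`` is the TreeQ of
    this cycle's search (``None`` if no action selected the tree system).
    """
    means = cache.means(state)
    vpis = vpi_values(cache, state, means)
    use_tree = vpis > arb.threshold
    iota = config.iota if config.intrinsic_enabled else 0.0
    tree = None
    if bool(use_tree.any()):
        tree = value_iteration(
            model,
            config.gamma,
            action_rewards,
            scope=config.scope,
            iota=iota,
            tol=config.vi_tol,
            max_sweeps=config.vi_max_sweeps,
            q_init=q_init,
        )
        q_tree = augmented_q(tree, model, state, iota, scope=config.scope)
        q_star = np.where(use_tree, q_tree, means)
    else:
        q_star = means.copy()
    systems = tuple("tree" if t else "cache" for t in use_tree)
    return q_star, systems, bool(use_tree.any()), tree


def act(q_star: np.ndarray, epsilon: float, rng: np.random.Generator) -> tuple[int, int]:
    """Greedy action (uniform over exact ties) and epsilon-greedy execution."""
    q = np.asarray(q_star, dtype=float).tolist()
    n = len(q)
    if n == 0:
        raise ValueError("q_star must be non-empty")
    cut = max(q) - 1e-12
    ties = [i for i, v in enumerate(q) if v >= cut]
    greedy = ties[rng.integers(len(ties))]
    if rng.random() < epsilon:
        executed = int(rng.integers(n))
    else:
        executed = greedy
    return greedy, executed


class Agent:
    """A complete learner bound to one task specification."""

    def __init__(self, spec: MDPSpec, config: AgentConfig):
        self.spec = spec
        self.config = config
        S, A = spec.n_obs, spec.n_actions
        self.cache = CacheQTable(S, A, prior=BetaDist(*config.cache_prior))
        self.model = WorldModel(
            S,
            A,
            transition_prior=config.transition_prior,
            reward_states=np.flatnonzero(spec.obs_rewarding),
            terminal_states=np.flatnonzero(spec.obs_terminal),
            reward_prior=BetaDist(*config.reward_prior),
            reward_active=config.reward_prior_active,
        )
        self.arb = ArbitrationState(
            eta=config.eta,
            tau=config.tau,
            mode=config.reward_mode,
            fixed_value=config.fixed_avg_reward,
        )
        self.rng = np.random.default_rng(config.seed)
        # pre-broadcast per-(state, action) action rewards for the planner
        self._action_reward_table = np.tile(spec.action_rewards, (S, 1))
        self.tree_search_count = 0
        self._warm_q: np.ndarray | None = None
        self.episode_summaries: list[EpisodeSummary] = []

    # -- one full cycle ----------------------------------------------------
    def step(self, env: Environment, episode: int = 0, step_index: int = 0) -> tuple[StepRecord, bool]:
        """Run one decision cycle; returns (record, episode_over)."""
        cfg = self.config
        s = env.obs
        q_star, systems, searched, tree = decide(
            s, self.cache, self.model, self.arb, cfg, self._action_reward_table, self._warm_q
        )
        if searched:
            self.tree_search_count += 1
            self._warm_q = tree.values
        greedy, executed = act(q_star, cfg.epsilon, self.rng)

        true2, obs2, r_ext, terminal, truncated = env.step(executed, self.rng)
        _, shift = observe_transition(self.model, s, executed, obs2)

        r_a = float(self.spec.action_rewards[executed])
        if terminal:
            cache_update(
                self.cache, s, executed, terminal_reward=r_ext, action_reward=r_a
            )
            update_reward(self.model, obs2, r_ext)
        else:
            a_best = int(np.argmax(self.cache.means(obs2)))
            cache_update(
                self.cache,
                s,
                executed,
                successor_best=self.cache.dist(obs2, a_best),
                action_reward=r_a,
                gamma=cfg.gamma,
            )
            if self.model.reward_mask[obs2]:
                # entering the lookalike of a goal without the episode ending
                # is evidence of a zero payout there
                update_reward(self.model, obs2, 0.0)

        update_avg_reward(self.arb, r_a + (r_ext if terminal else 0.0))

        if cfg.theta < 1.0:
            self.cache.decay(cfg.theta)
            self.model.decay(cfg.theta)

        iota = cfg.iota if cfg.intrinsic_enabled else 0.0
        record = StepRecord(
            episode=episode,
            step=step_index,
            obs_state=s,
            greedy_action=greedy,
            executed_action=executed,
            systems=systems,
            searched=searched,
            tree_search_count=self.tree_search_count,
            extrinsic_reward=r_ext if terminal else 0.0,
            intrinsic_reward=iota * shift,
            avg_reward=self.arb.effective_avg_reward,
        )
        return record, terminal or truncated

    def apply_devaluation(self, env: Environment, event: Devaluation) -> None:
        """Devalue both the delivered payouts and the agent's reward model."""
        env.devalue(event.true_states, event.new_reward)
        for o in obs_states_for_devaluation(self.spec, event.true_states):
            devalue_state(self.model, o, event.new_reward)

    def run_episodes(
        self,
        env: Environment,
        n_episodes: int,
        devaluation_schedule: dict | None = None,
    ) -> list[StepRecord]:
        """Run episodes, applying scheduled devaluations between them.

        ``devaluation_schedule`` maps an episode count k to events applied
        after k episodes have completed (i.e. before episode index k).
        """
        schedule = devaluation_schedule or {}
        records: list[StepRecord] = []
        for ep in range(n_episodes):
            for event in schedule.get(ep, ()):
                self.apply_devaluation(env, event)
            env.reset(self.rng)
            step_index = 0
            done = False
            total_r = 0.0
            while not done:
                rec, done = self.step(env, episode=ep, step_index=step_index)
                records.append(rec)
                total_r += rec.extrinsic_reward
                step_index += 1
            self.episode_summaries.append(
                EpisodeSummary(
                    episode=ep,
                    n_steps=step_index,
                    terminal_true_state=env.true_state
                    if self.spec.terminal[env.true_state]
                    else None,
                    extrinsic_reward=total_r,
                )
            )
        return records
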