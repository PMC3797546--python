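"""Tabular task definitions: the two-step feeder and the Playroom.

Both tasks are explicit MDPs over enumerated *true* states with an observation
map.  The dynamics always evolve on true states; every learning structure of
the agent is indexed by observed states, which is what makes the dark-room
box ambiguity of the Playroom behaviourally relevant.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .bayes_core import BetaDist

__all__ = [
    "MDPSpec",
    "Environment",
    "Devaluation",
    "GoalSpec",
    "PlayroomState",
    "PLAYROOM_OBJECTS",
    "PLAYROOM_ACTIONS",
    "make_feeder",
    "make_playroom",
    "observe",
    "terminal_states_matching",
    "obs_states_for_devaluation",
    "min_steps_to_goal",
    "spec_to_dict",
    "spec_from_dict",
]

PLAYROOM_OBJECTS = ("blue_box", "red_box", "switch", "monkey")
PLAYROOM_ACTIONS = ("use", "eye_to_random", "hand_to_eye", "null")
BOXES = ("blue_box", "red_box")


@dataclass(frozen=True)
class PlayroomState:
    """Underlying Playroom state: hand/eye position plus light and music flags."""

    hand: str
    eye: str
    light: bool
    music: bool


@dataclass(frozen=True)
class GoalSpec:
    """Goal condition: required music/light values plus optional hand/eye sets."""

    music: bool | None = None
    light: bool | None = None
    hand: frozenset | None = None
    eye: frozenset | None = None

    def __post_init__(self):
        if self.music is None and self.light is None and self.hand is None and self.eye is None:
            raise ValueError("goal must constrain at least one state component")
        for attr in ("hand", "eye"):
            val = getattr(self, attr)
            if val is not None:
                val = frozenset(val)
                if not val or not val.issubset(PLAYROOM_OBJECTS):
                    raise ValueError(f"invalid {attr} constraint: {val}")
                object.__setattr__(self, attr, val)

    def matches(self, s: PlayroomState) -> bool:
        if self.music is not None and s.music != self.music:
            return False
        if self.light is not None and s.light != self.light:
            return False
        if self.hand is not None and s.hand not in self.hand:
            return False
        if self.eye is not None and s.eye not in self.eye:
            return False
        return True


@dataclass
class MDPSpec:
    """Explicit tabular MDP with an observation map.

    ``terminal_reward[s]`` is ``None`` for non-terminal states, a float for a
    deterministic terminal payout, or a :class:`BetaDist` the payout is sampled
    from (used after devaluation).
    """

    name: str
    state_labels: list
    actions: list
    P: np.ndarray  # (nS, nA, nS) true dynamics
    action_rewards: np.ndarray  # (nA,)
    terminal: np.ndarray  # (nS,) bool
    terminal_reward: list  # per true state: None | float | BetaDist
    start: int
    obs_of_state: np.ndarray  # (nS,) int
    obs_labels: list
    step_cap: int = 100

    # derived, filled in __post_init__
    n_states: int = field(init=False)
    n_actions: int = field(init=False)
    n_obs: int = field(init=False)
    obs_terminal: np.ndarray = field(init=False)   # all terminal preimages
    obs_rewarding: np.ndarray = field(init=False)  # some terminal preimage

    def __post_init__(self):
        self.n_states = len(self.state_labels)
        self.n_actions = len(self.actions)
        self.P = np.asarray(self.P, dtype=float)
        self.action_rewards = np.asarray(self.action_rewards, dtype=float)
        self.terminal = np.asarray(self.terminal, dtype=bool)
        self.obs_of_state = np.asarray(self.obs_of_state, dtype=np.int64)
        self.n_obs = len(self.obs_labels)
        if self.P.shape != (self.n_states, self.n_actions, self.n_states):
            raise ValueError("transition tensor shape mismatch")
        rows = self.P[~self.terminal]
        if rows.size and not np.allclose(rows.sum(axis=-1), 1.0):
            raise ValueError("non-terminal transition rows must sum to 1")
        if np.any(self.P[self.terminal] != 0.0):
            raise ValueError("terminal states must have no outgoing transitions")
        self.obs_terminal = np.zeros(self.n_obs, dtype=bool)
        self.obs_rewarding = np.zeros(self.n_obs, dtype=bool)
        for o in range(self.n_obs):
            pre = self.obs_of_state == o
            self.obs_rewarding[o] = bool(np.any(self.terminal & pre))
            self.obs_terminal[o] = bool(np.any(pre)) and bool(np.all(self.terminal[pre]))
        # precompute successor samplers: int for deterministic rows,
        # (support, cumprobs) otherwise
        self._succ: list = [[None] * self.n_actions for _ in range(self.n_states)]
        for s in range(self.n_states):
            if self.terminal[s]:
                continue
            for a in range(self.n_actions):
                row = self.P[s, a]
                nz = np.flatnonzero(row)
                if nz.size == 1:
                    self._succ[s][a] = int(nz[0])
                else:
                    self._succ[s][a] = (nz, np.cumsum(row[nz]))

    def action_index(self, action) -> int:
        return action if isinstance(action, (int, np.integer)) else self.actions.index(action)

    def state_index(self, label) -> int:
        return label if isinstance(label, (int, np.integer)) else self.state_labels.index(label)


def observe(spec: MDPSpec, state: int) -> int:
    """Observed-state index for a true state."""
    return int(spec.obs_of_state[state])


class Environment:
    """Stateful wrapper around an :class:`MDPSpec` for episodic interaction."""

    def __init__(self, spec: MDPSpec):
        self.spec = spec
        self.true_state: int | None = None
        self.obs: int | None = None
        self.steps = 0

    def reset(self, rng: np.random.Generator) -> tuple[int, int]:
        self.true_state = self.spec.start
        if self.spec.terminal[self.true_state]:
            raise ValueError("start state must not be terminal")
        self.obs = observe(self.spec, self.true_state)
        self.steps = 0
        return self.true_state, self.obs

    def _terminal_reward(self, s: int, rng: np.random.Generator) -> float:
        r = self.spec.terminal_reward[s]
        if r is None:
            return 0.0
        if isinstance(r, BetaDist):
            return float(rng.beta(r.alpha, r.beta))
        return float(r)

    def step(self, action: int, rng: np.random.Generator):
        """Execute an action; returns (true', obs', extrinsic_reward, terminal, truncated)."""
        if self.true_state is None:
            raise RuntimeError("call reset() before step()")
        succ = self.spec._succ[self.true_state][action]
        if isinstance(succ, int):
            s2 = succ
        else:
            support, cum = succ
            s2 = int(support[np.searchsorted(cum, rng.random(), side="right")])
        self.steps += 1
        self.true_state = s2
        self.obs = observe(self.spec, s2)
        terminal = bool(self.spec.terminal[s2])
        reward = self._terminal_reward(s2, rng) if terminal else 0.0
        truncated = (not terminal) and self.steps >= self.spec.step_cap
        return s2, self.obs, reward, terminal, truncated

    def devalue(self, true_states: Iterable[int], new_reward: BetaDist) -> None:
        """Replace the delivered terminal reward of the given states."""
        for s in true_states:
            if not self.spec.terminal[s]:
                raise KeyError(f"state {s} is not terminal")
            self.spec.terminal_reward[s] = new_reward


@dataclass(frozen=True)
class Devaluation:
    """A scheduled change of terminal payouts (environment and reward model)."""

    true_states: tuple
    new_reward: BetaDist


# ---------------------------------------------------------------------------
# Feeder task
# ---------------------------------------------------------------------------

def make_feeder(variant: str = "simple") -> MDPSpec:
    """Two-decision feeder task.

    ``simple``: actions press/entry; press then entry pays out, anything else
    restarts unrewarded.  ``moderate``: adds a chain action whose chain-then-
    entry sequence reaches a distinct but equally rewarded terminal.
    """
    if variant == "simple":
        labels = ["S0", "S1", "T+", "T0"]
        actions = ["press", "entry"]
        edges = {("S0", "press"): "S1", ("S0", "entry"): "T0",
                 ("S1", "entry"): "T+", ("S1", "press"): "T0"}
        rewarded = {"T+": 1.0, "T0": 0.0}
    elif variant == "moderate":
        labels = ["S0", "S1", "S2", "T+", "T+'", "T0"]
        actions = ["press", "entry", "chain"]
        edges = {("S0", "press"): "S1", ("S0", "chain"): "S2", ("S0", "entry"): "T0",
                 ("S1", "entry"): "T+", ("S1", "press"): "T0", ("S1", "chain"): "T0",
                 ("S2", "entry"): "T+'", ("S2", "press"): "T0", ("S2", "chain"): "T0"}
        rewarded = {"T+": 1.0, "T+'": 1.0, "T0": 0.0}
    else:
        raise ValueError(f"unknown feeder variant {variant!r}")

    idx = {lab: i for i, lab in enumerate(labels)}
    nS, nA = len(labels), len(actions)
    P = np.zeros((nS, nA, nS))
    for (s, a), s2 in edges.items():
        P[idx[s], actions.index(a), idx[s2]] = 1.0
    terminal = np.array([lab in rewarded for lab in labels])
    terminal_reward = [rewarded.get(lab) for lab in labels]
    return MDPSpec(
        name=f"feeder-{variant}",
        state_labels=labels,
        actions=actions,
        P=P,
        action_rewards=np.zeros(nA),
        terminal=terminal,
        terminal_reward=terminal_reward,
        start=idx["S0"],
        obs_of_state=np.arange(nS),
        obs_labels=list(labels),
        step_cap=10,
    )


# ---------------------------------------------------------------------------
# Playroom task
# ---------------------------------------------------------------------------

DEFAULT_PLAYROOM_START = PlayroomState(hand="monkey", eye="monkey", light=False, music=False)


def _playroom_states() -> list[PlayroomState]:
    return [
        PlayroomState(h, e, bool(l), bool(m))
        for h, e, l, m in itertools.product(PLAYROOM_OBJECTS, PLAYROOM_OBJECTS, (0, 1), (0, 1))
    ]


def _playroom_obs_label(s: PlayroomState):
    if s.light:
        return ("lit", s.hand, s.eye, s.music)
    merge = lambda o: "some_box" if o in BOXES else o
    return ("dark", merge(s.hand), merge(s.eye), s.music)


def _use_effect(s: PlayroomState) -> PlayroomState:
    if s.hand != s.eye:
        return s
    obj = s.hand
    if obj == "blue_box":
        return PlayroomState(s.hand, s.eye, s.light, True)
    if obj == "red_box":
        return PlayroomState(s.hand, s.eye, s.light, False)
    if obj == "switch":
        return PlayroomState(s.hand, s.eye, not s.light, s.music)
    return s  # monkey: neutral distractor


def make_playroom(
    goal: GoalSpec | None = None,
    start: PlayroomState = DEFAULT_PLAYROOM_START,
    step_cap: int = 100,
) -> MDPSpec:
    """Playroom task: hand/eye over four objects, light and music toggles.

    An object only responds to ``use`` when hand and eye both rest on it.
    ``eye_to_random`` moves the eye uniformly over all four objects (the one
    nondeterministic action).  With the light off the two boxes become
    observationally indistinguishable.  ``goal=None`` yields a task without
    terminal states (pure free play).
    """
    states = _playroom_states()
    idx = {s: i for i, s in enumerate(states)}
    nS, nA = len(states), len(PLAYROOM_ACTIONS)
    terminal = np.array([goal.matches(s) if goal is not None else False for s in states])

    P = np.zeros((nS, nA, nS))
    for i, s in enumerate(states):
        if terminal[i]:
            continue
        P[i, 0, idx[_use_effect(s)]] += 1.0
        for obj in PLAYROOM_OBJECTS:  # eye_to_random may land on the current object
            P[i, 1, idx[PlayroomState(s.hand, obj, s.light, s.music)]] += 0.25
        P[i, 2, idx[PlayroomState(s.eye, s.eye, s.light, s.music)]] += 1.0
        P[i, 3, i] += 1.0  # null

    obs_labels: list = []
    obs_index: dict = {}
    obs_of_state = np.empty(nS, dtype=np.int64)
    for i, s in enumerate(states):
        lab = _playroom_obs_label(s)
        if lab not in obs_index:
            obs_index[lab] = len(obs_labels)
            obs_labels.append(lab)
        obs_of_state[i] = obs_index[lab]

    return MDPSpec(
        name="playroom",
        state_labels=states,
        actions=list(PLAYROOM_ACTIONS),
        P=P,
        action_rewards=np.array([-0.02, -0.02, -0.02, 0.005]),
        terminal=terminal,
        terminal_reward=[1.0 if t else None for t in terminal],
        start=idx[start],
        obs_of_state=obs_of_state,
        obs_labels=obs_labels,
        step_cap=step_cap,
    )


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def terminal_states_matching(spec: MDPSpec, predicate: Callable) -> list[int]:
    """Indices of terminal true states whose label satisfies ``predicate``."""
    return [
        i for i in range(spec.n_states)
        if spec.terminal[i] and predicate(spec.state_labels[i])
    ]


def obs_states_for_devaluation(spec: MDPSpec, true_states: Sequence[int]) -> list[int]:
    """Observed states whose *entire* terminal preimage is being devalued.

    Only those reward-model entries can be reset consistently; a mixed
    observed state would conflate devalued and intact outcomes.
    """
    devalued = set(int(s) for s in true_states)
    out = []
    for o in range(spec.n_obs):
        pre = np.flatnonzero((spec.obs_of_state == o) & spec.terminal)
        if pre.size and all(int(s) in devalued for s in pre):
            out.append(o)
    return out


def min_steps_to_goal(spec: MDPSpec, goal_states: Sequence[int] | None = None) -> int:
    """Shortest action count from start to a (subset of) terminal state(s).

    Nondeterministic actions are treated optimistically: any positive-
    probability successor counts as reachable in one step.
    """
    targets = set(
        int(s) for s in (goal_states if goal_states is not None else np.flatnonzero(spec.terminal))
    )
    if not targets:
        raise ValueError("no goal states")
    seen = {spec.start}
    queue = deque([(spec.start, 0)])
    while queue:
        s, d = queue.popleft()
        if s in targets:
            return d
        for a in range(spec.n_actions):
            for s2 in np.flatnonzero(spec.P[s, a]):
                if int(s2) not in seen:
                    seen.add(int(s2))
                    queue.append((int(s2), d + 1))
    raise ValueError("goal unreachable from start")


# ---------------------------------------------------------------------------
# Serialization (plain-JSON friendly)
# ---------------------------------------------------------------------------

def _reward_to_jsonable(r):
    if r is None:
        return None
    if isinstance(r, BetaDist):
        return {"beta": [r.alpha, r.beta]}
    return float(r)


def _reward_from_jsonable(r):
    if r is None:
        return None
    if isinstance(r, dict):
        a, b = r["beta"]
        return BetaDist(a, b)
    return float(r)


def spec_to_dict(spec: MDPSpec) -> dict:
    return {
        "name": spec.name,
        "state_labels": [str(lab) for lab in spec.state_labels],
        "actions": list(spec.actions),
        "P": spec.P.tolist(),
        "action_rewards": spec.action_rewards.tolist(),
        "terminal": spec.terminal.astype(int).tolist(),
        "terminal_reward": [_reward_to_jsonable(r) for r in spec.terminal_reward],
        "start": int(spec.start),
        "obs_of_state": spec.obs_of_state.tolist(),
        "obs_labels": [str(lab) for lab in spec.obs_labels],
        "step_cap": int(spec.step_cap),
    }


def spec_from_dict(d: dict) -> MDPSpec:
    return MDPSpec(
        name=d["name"],
        state_labels=list(d["state_labels"]),
        actions=list(d["actions"]),
        P=np.asarray(d["P"], dtype=float),
        action_rewards=np.asarray(d["action_rewards"], dtype=float),
        terminal=np.asarray(d["terminal"], dtype=bool),
        terminal_reward=[_reward_from_jsonable(r) for r in d["terminal_reward"]],
        start=int(d["start"]),
        obs_of_state=np.asarray(d["obs_of_state"], dtype=np.int64),
        obs_labels=list(d["obs_labels"]),
        step_cap=int(d["step_cap"]),
    )
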