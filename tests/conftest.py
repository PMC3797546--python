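import numpy as np
import pytest
from hypothesis import settings

from dualsys.bayes_core import BetaDist
from dualsys.environments import MDPSpec

# deterministic example generation so CI runs are reproducible
settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_chain_spec() -> MDPSpec:
    """Deterministic 2-step chain S0 -press-> S1 -entry-> T with reward 1.

    Both actions exist everywhere; the off-path action leads to an unrewarded
    terminal.  Used as the hand-checkable planning fixture.
    """
    labels = ["S0", "S1", "T", "T0"]
    actions = ["press", "entry"]
    P = np.zeros((4, 2, 4))
    P[0, 0, 1] = 1.0  # S0 press -> S1
    P[0, 1, 3] = 1.0  # S0 entry -> T0
    P[1, 1, 2] = 1.0  # S1 entry -> T
    P[1, 0, 3] = 1.0  # S1 press -> T0
    return MDPSpec(
        name="chain",
        state_labels=labels,
        actions=actions,
        P=P,
        action_rewards=np.array([-0.02, -0.02]),
        terminal=np.array([False, False, True, True]),
        terminal_reward=[None, None, 1.0, 0.0],
        start=0,
        obs_of_state=np.arange(4),
        obs_labels=labels,
        step_cap=10,
    )


@pytest.fixture
def chain_spec():
    return make_chain_spec()


def random_mdp_spec(rng: np.random.Generator, n_states=5, n_actions=3) -> MDPSpec:
    """A small random MDP with one rewarded and one unrewarded terminal."""
    labels = [f"s{i}" for i in range(n_states)]
    terminal = np.zeros(n_states, dtype=bool)
    terminal[-2:] = True
    P = np.zeros((n_states, n_actions, n_states))
    for s in range(n_states - 2):
        for a in range(n_actions):
            row = rng.dirichlet(np.ones(n_states))
            P[s, a] = row
    rewards = [None] * n_states
    rewards[-2] = 1.0
    rewards[-1] = 0.0
    return MDPSpec(
        name="random",
        state_labels=labels,
        actions=[f"a{j}" for j in range(n_actions)],
        P=P,
        action_rewards=rng.uniform(-0.05, 0.05, n_actions),
        terminal=terminal,
        terminal_reward=rewards,
        start=0,
        obs_of_state=np.arange(n_states),
        obs_labels=labels,
        step_cap=50,
    )


def grid_beta_pdf(d: BetaDist, n: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint grid and density values for brute-force integration oracles."""
    x = (np.arange(n) + 0.5) / n
    return x, d.pdf(x)
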