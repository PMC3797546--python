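# dualsys

A tabular, fully Bayesian dual-system reinforcement-learning simulator: a
model-free "habitual" controller (Beta posteriors over cached action values)
competes per action with a model-based "goal-directed" controller (Dirichlet
transition model + Beta reward model, value iteration to convergence). The
value of perfect information computed from the cache posterior is weighed
against the opportunity cost of deliberation (average reward × search cost);
the goal-directed system additionally earns learning-progress intrinsic
rewards from shifts in its transition model. Two built-in tasks — a
two-decision feeder and a Playroom with partially observable object
manipulation — support scripted experiments on outcome devaluation,
intrinsically motivated activity, post-extinction suppression, model
acquisition, and promised-reward effects.

## Layout

| Module | Contents |
| --- | --- |
| `dualsys.bayes_core` | Beta/Dirichlet types; moments, variance-increasing mean reshaping, moment-matched mixture updates, exponential forgetting |
| `dualsys.habitual_cache` | Cache Q-table with bootstrapped, cost-adjusted Beta updates |
| `dualsys.goal_tree` | World model, intrinsic (learning-progress) rewards, value iteration, devaluation |
| `dualsys.arbitration` | Gain/VPI, tree-vs-cache selection, average-reward tracking with a fixed "promised reward" mode |
| `dualsys.agent` | The decision loop: per-action arbitration, ε-greedy choice, learning updates, forgetting, trace logging |
| `dualsys.environments` | Feeder (simple/moderate) and Playroom MDP specs, observation maps, JSON serialization |
| `dualsys.experiments` | Seeded multi-run experiment families, metrics, paired sign tests |

## CLI

Each experiment family is a subcommand writing per-run metric CSVs plus a
config echo JSON into `--out`:

```bash
dualsys feeder-deval    --runs 30 --seed 0 --out results/
dualsys activity        --runs 30 --seed 0 --out results/
dualsys post-extinction --runs 30 --seed 0 --out results/
dualsys scope           --runs 30 --seed 0 --out results/
dualsys acquisition     --runs 30 --seed 0 --out results/
dualsys promised        --runs 30 --seed 0 --out results/
```

Keyword overrides (episode counts, step caps, ε grids, ...) can be supplied
with `--config overrides.json` (or `.yaml`).

## Library example

```python
from dualsys import Agent, AgentConfig, Environment, make_feeder

spec = make_feeder("simple")
agent = Agent(spec, AgentConfig.feeder_defaults(seed=1))
records = agent.run_episodes(Environment(spec), n_episodes=200)
```

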