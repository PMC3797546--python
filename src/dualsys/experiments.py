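"""Seeded reproductions of the devaluation, activity and performance studies.

Each public function runs one experiment family across paired seeds and
returns raw per-run metrics as a DataFrame; directional claims are evaluated
with paired sign tests, reported rather than hard-coded.  All smoothing is
left to plotting code — stored metrics are raw ratios.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .agent import Agent, AgentConfig, StepRecord
from .bayes_core import BetaDist
from .environments import (
    DEFAULT_PLAYROOM_START,
    Devaluation,
    Environment,
    GoalSpec,
    PlayroomState,
    make_feeder,
    make_playroom,
    terminal_states_matching,
)

__all__ = [
    "DEVALUED_REWARD",
    "GOAL_MUSIC_DARK",
    "GOAL_MUSIC_DARK_BLUE_EYE",
    "PROXIMAL_START",
    "sign_test",
    "run_feeder_once",
    "run_playroom_once",
    "feeder_devaluation",
    "activity_experiments",
    "model_acquisition",
    "promised_rewards",
]

DEVALUED_REWARD = BetaDist(1.0, 15.0)
GOAL_MUSIC_DARK = GoalSpec(music=True, light=False)
GOAL_MUSIC_DARK_BLUE_EYE = GoalSpec(music=True, light=False, eye=frozenset({"blue_box"}))
PROXIMAL_START = PlayroomState(hand="monkey", eye="monkey", light=True, music=True)


def sign_test(greater, lesser) -> float:
    """One-sided paired sign test p-value for H1: greater > lesser.

    Ties are dropped, as usual for the sign test.
    """
    g = np.asarray(greater, dtype=float)
    l = np.asarray(lesser, dtype=float)
    if g.shape != l.shape:
        raise ValueError("paired samples must have equal length")
    diff = g - l
    n = int(np.sum(diff != 0))
    if n == 0:
        return 1.0
    k = int(np.sum(diff > 0))
    return float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# Single-run drivers
# ---------------------------------------------------------------------------

def run_feeder_once(
    variant: str,
    n_episodes: int,
    deval_episode: int | None,
    seed: int,
    config: AgentConfig | None = None,
) -> dict:
    """One feeder run; returns per-episode start-state decision metrics.

    ``press``: greedy first-decision action was the lever press (recorded
    before exploration).  ``habitual``: the system backing that greedy action
    was the cache.
    """
    spec = make_feeder(variant)
    cfg = config or AgentConfig.feeder_defaults(seed=seed)
    env = Environment(spec)
    agent = Agent(spec, cfg)
    schedule = {}
    if deval_episode is not None:
        target = spec.state_index("T+")  # the press-route terminal
        schedule = {deval_episode: [Devaluation((target,), DEVALUED_REWARD)]}
    records = agent.run_episodes(env, n_episodes, schedule)

    press_idx = spec.actions.index("press")
    press = np.zeros(n_episodes, dtype=bool)
    habitual = np.zeros(n_episodes, dtype=bool)
    for rec in records:
        if rec.step == 0:  # the (only) start-state decision of the episode
            press[rec.episode] = rec.greedy_action == press_idx
            habitual[rec.episode] = rec.systems[rec.greedy_action] == "cache"
    return {"press": press, "habitual": habitual}


def run_playroom_once(
    seed: int,
    n_episodes: int,
    goal: GoalSpec | None,
    deval_episode: int | None = None,
    deval_predicate=None,
    intrinsic: bool = True,
    scope: str = "local",
    reward_mode: str = "observed",
    epsilon: float = 0.2,
    start: PlayroomState = DEFAULT_PLAYROOM_START,
    step_cap: int = 100,
    config_overrides: dict | None = None,
) -> pd.DataFrame:
    """One Playroom run; returns one row per episode.

    Columns: ``activity`` (fraction of greedy non-null choices, recorded
    before exploration), ``steps``, ``reached`` (ended at a terminal state),
    ``terminal_true`` (true-state index or -1), ``searches`` (cumulative tree
    searches at episode end).
    """
    spec = make_playroom(goal=goal, start=start, step_cap=step_cap)
    overrides = dict(config_overrides or {})
    cfg = AgentConfig.playroom_defaults(
        seed=seed,
        intrinsic_enabled=intrinsic,
        scope=scope,
        reward_mode=reward_mode,
        epsilon=epsilon,
        **overrides,
    )
    env = Environment(spec)
    agent = Agent(spec, cfg)
    schedule = {}
    if deval_episode is not None:
        pred = deval_predicate if deval_predicate is not None else (lambda s: True)
        targets = terminal_states_matching(spec, pred)
        schedule = {deval_episode: [Devaluation(tuple(targets), DEVALUED_REWARD)]}
    records = agent.run_episodes(env, n_episodes, schedule)

    null_idx = spec.actions.index("null")
    episodes = np.fromiter((r.episode for r in records), dtype=np.int64, count=len(records))
    nonnull = np.fromiter(
        (r.greedy_action != null_idx for r in records), dtype=np.float64, count=len(records)
    )
    counts = np.bincount(episodes, minlength=n_episodes)
    sums = np.bincount(episodes, weights=nonnull, minlength=n_episodes)
    activity = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)

    summ = agent.episode_summaries
    return pd.DataFrame(
        {
            "episode": np.arange(n_episodes),
            "activity": activity,
            "steps": [s.n_steps for s in summ],
            "reached": [s.terminal_true_state is not None for s in summ],
            "terminal_true": [
                -1 if s.terminal_true_state is None else s.terminal_true_state for s in summ
            ],
            "searches": _searches_per_episode(records, n_episodes),
        }
    )


def _searches_per_episode(records: list[StepRecord], n_episodes: int) -> np.ndarray:
    out = np.zeros(n_episodes, dtype=np.int64)
    for rec in records:  # the last record of each episode wins
        out[rec.episode] = rec.tree_search_count
    return out


# ---------------------------------------------------------------------------
# Experiment families
# ---------------------------------------------------------------------------

def _seeds(seed: int, n_runs: int) -> np.ndarray:
    return seed + np.arange(n_runs)


def feeder_devaluation(
    n_runs: int = 30,
    seed: int = 0,
    late_episode: int = 200,
    early_episode: int = 20,
    moderate_episode: int = 240,
    late_window: int = 100,
    early_window: int = 20,
) -> pd.DataFrame:
    """Devaluation-resistance battery on the feeder task.

    Per seed: relative post/pre press frequency for the early, late and
    moderate settings, plus habitual-selection ratios in the start state for
    the windows used by the comparisons.
    """
    rows = []
    for s in _seeds(seed, n_runs):
        early = run_feeder_once(
            "simple", early_episode + early_window, early_episode, int(s)
        )
        late = run_feeder_once("simple", late_episode + late_window, late_episode, int(s))
        mod = run_feeder_once(
            "moderate", moderate_episode + late_window, moderate_episode, int(s)
        )

        rows.append(
            {
                "seed": int(s),
                "rel_press_early": _rel_rate(early["press"], early_episode, early_window),
                "rel_press_late": _rel_rate(late["press"], late_episode, late_window),
                "rel_press_moderate": _rel_rate(mod["press"], moderate_episode, late_window),
                "rel_press_moderate_20": _rel_rate(mod["press"], moderate_episode, 20),
                "hab_start_early": late["habitual"][:early_episode].mean(),
                "hab_start_late": late["habitual"][
                    late_episode - early_episode : late_episode
                ].mean(),
                "hab_start_moderate": mod["habitual"][
                    moderate_episode - early_episode : moderate_episode
                ].mean(),
            }
        )
    return pd.DataFrame(rows)


def _rel_rate(flags: np.ndarray, pivot: int, window: int) -> float:
    pre = flags[max(pivot - window, 0) : pivot].mean()
    post = flags[pivot : pivot + window].mean()
    return float(post / pre) if pre > 0 else np.nan


def activity_experiments(
    n_runs: int = 30,
    seed: int = 0,
    condition: str = "activity",
    n_episodes: int = 250,
    deval_episode: int = 50,
    step_cap: int = 100,
) -> pd.DataFrame:
    """Playroom activity studies; returns per-(seed, condition, episode) rows.

    ``activity``: free play with vs. without intrinsic rewards.
    ``post-extinction``: extrinsic goal devalued mid-run vs. the purely
    intrinsic baseline.
    ``scope``: local vs. global intrinsic rewards around a devaluation.
    """
    if condition == "activity":
        variants = {
            "intrinsic": dict(goal=None, intrinsic=True),
            "no-intrinsic": dict(goal=None, intrinsic=False),
        }
    elif condition == "post-extinction":
        variants = {
            "intrinsic-only": dict(goal=None, intrinsic=True),
            "extrinsic-deval": dict(goal=GOAL_MUSIC_DARK, intrinsic=True, deval_episode=deval_episode),
        }
    elif condition == "scope":
        variants = {
            "local": dict(
                goal=GOAL_MUSIC_DARK, intrinsic=True, deval_episode=deval_episode, scope="local"
            ),
            "global": dict(
                goal=GOAL_MUSIC_DARK, intrinsic=True, deval_episode=deval_episode, scope="global"
            ),
        }
    else:
        raise ValueError(f"unknown condition {condition!r}")

    frames = []
    for s in _seeds(seed, n_runs):
        for name, kw in variants.items():
            df = run_playroom_once(int(s), n_episodes, step_cap=step_cap, **kw)
            df.insert(0, "condition", name)
            df.insert(0, "seed", int(s))
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def not_switch_route(state) -> bool:
    """Devaluation predicate: every goal entry except hand and eye on the switch."""
    return not (state.hand == "switch" and state.eye == "switch")


def is_switch_route(state) -> bool:
    return state.hand == "switch" and state.eye == "switch"


def model_acquisition(
    n_runs: int = 30,
    seed: int = 0,
    epsilons=(0.0, 0.05, 0.1, 0.2, 0.3, 0.5),
    train_episodes: int = 200,
    test_episodes: int = 100,
    step_cap: int = 150,
) -> pd.DataFrame:
    """Distal-goal acquisition after devaluing the proximal route.

    The goal (music on, light off) is trained, then all goal entries except
    hand-and-eye-on-switch are devalued; the metric counts test episodes that
    end on the remaining distal entry.  The longer default step cap gives
    episodes enough room for the nine-action detour to be stumbled upon.
    """
    spec = make_playroom(goal=GOAL_MUSIC_DARK)
    distal = set(terminal_states_matching(spec, is_switch_route))
    rows = []
    for s in _seeds(seed, n_runs):
        for eps in epsilons:
            for cond, intrinsic in (("intrinsic", True), ("extrinsic-only", False)):
                df = run_playroom_once(
                    int(s),
                    train_episodes + test_episodes,
                    GOAL_MUSIC_DARK,
                    deval_episode=train_episodes,
                    deval_predicate=not_switch_route,
                    intrinsic=intrinsic,
                    epsilon=float(eps),
                    step_cap=step_cap,
                )
                test = df[df["episode"] >= train_episodes]
                rows.append(
                    {
                        "seed": int(s),
                        "epsilon": float(eps),
                        "condition": cond,
                        "distal_count": int(test["terminal_true"].isin(distal).sum()),
                    }
                )
    return pd.DataFrame(rows)


def promised_rewards(
    n_runs: int = 30,
    seed: int = 0,
    n_episodes: int = 300,
    final_window: int = 50,
    step_cap: int = 100,
) -> pd.DataFrame:
    """Promised (fixed average reward) vs. observed reward expectation.

    The goal requires music on, light off and the eye on the blue box; the
    proximal setting starts with light and music already on, the distal one
    in the dark with music off.
    """
    rows = []
    for s in _seeds(seed, n_runs):
        for setting, start in (("proximal", PROXIMAL_START), ("distal", DEFAULT_PLAYROOM_START)):
            for mode in ("observed", "fixed"):
                df = run_playroom_once(
                    int(s),
                    n_episodes,
                    GOAL_MUSIC_DARK_BLUE_EYE,
                    reward_mode=mode,
                    start=start,
                    step_cap=step_cap,
                )
                final = df[df["episode"] >= n_episodes - final_window]
                rows.append(
                    {
                        "seed": int(s),
                        "setting": setting,
                        "mode": mode,
                        "reach_rate": float(df["reached"].mean()),
                        "reach_rate_final": float(final["reached"].mean()),
                        "searches_total": int(df["searches"].iloc[-1]),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_outputs(
    df: pd.DataFrame, out_dir: str | Path, name: str, config: dict, plot: bool = False
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    with open(out / f"{name}_config.json", "w") as fh:
        json.dump(config, fh, indent=2, default=str)
    if plot:
        plot_metrics(df, out / f"{name}.png")


def plot_metrics(df: pd.DataFrame, path: str | Path) -> None:
    """Quick-look PNG of the main metric; purely cosmetic, never asserted on."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    if {"condition", "episode", "activity"} <= set(df.columns):
        for cond, grp in df.groupby("condition"):
            series = grp.groupby("episode")["activity"].mean()
            ax.plot(series.index, series.values, label=str(cond))
        ax.set_xlabel("episode")
        ax.set_ylabel("mean non-null greedy fraction")
        ax.legend()
    else:
        numeric = df.select_dtypes("number").drop(columns=["seed"], errors="ignore")
        numeric.mean().plot.bar(ax=ax)
        ax.set_ylabel("mean over runs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
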