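"""Per-action competition between the cache and the tree system.

Each action's value of perfect information (expected policy improvement from
learning its true value) is computed from the cache posterior alone and
compared against the opportunity cost of deliberation, the average reward
times the per-edge search cost.  A "fixed" mode pins the average reward at a
promised level instead of tracking observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .habitual_cache import CacheQTable, best_and_second

__all__ = [
    "ArbitrationState",
    "gain",
    "vpi",
    "vpi_values",
    "select_system",
    "update_avg_reward",
]


@dataclass
class ArbitrationState:
    """Average-reward tracker and arbitration constants."""

    avg_reward: float = 0.0
    eta: float = 0.001
    tau: float = 0.1
    mode: str = "observed"  # "observed" | "fixed"
    fixed_value: float = 1.0
    backend: str = "exact"  # "exact" | "grid" | "mc"
    nodes: int = 512

    def __post_init__(self):
        if self.mode not in ("observed", "fixed"):
            raise ValueError(f"mode must be 'observed' or 'fixed', got {self.mode!r}")
        if not (0.0 < self.eta < 1.0):
            raise ValueError("eta must lie in (0, 1)")
        if self.tau < 0.0:
            raise ValueError("tau must be non-negative")

    @property
    def effective_avg_reward(self) -> float:
        return self.fixed_value if self.mode == "fixed" else self.avg_reward

    @property
    def threshold(self) -> float:
        return self.effective_avg_reward * self.tau


def gain(x: float, best_mean: float, second_mean: float, is_best: bool) -> float:
    """Policy improvement if the action's true value turned out to be ``x``."""
    if is_best:
        return second_mean - x if x < second_mean else 0.0
    return x - best_mean if x > best_mean else 0.0


def _vpi_exact(a, b, c, is_best):
    """Closed-form expected gain under Beta(a, b) with threshold c.

    Uses E[x 1{x<=c}] = mean * I_c(a+1, b) with the regularized incomplete
    beta function, so the piecewise-linear gain integrates exactly.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    mu = a / (a + b)
    F = special.betainc(a, b, c)
    F1 = special.betainc(a + 1.0, b, c)
    below = c * F - mu * F1          # E[(c - x)+], the best-action branch
    above = mu * (1.0 - F1) - c * (1.0 - F)  # E[(x - c)+]
    out = np.where(is_best, below, above)
    return np.maximum(out, 0.0)


def vpi(
    cache: CacheQTable,
    state: int,
    action: int,
    *,
    backend: str = "exact",
    nodes: int = 512,
    rng: np.random.Generator | None = None,
) -> float:
    """Value of perfect information for one action, from the cache posterior.

    ``backend="exact"`` evaluates the integral in closed form; ``"grid"`` uses
    a fixed midpoint rule with ``nodes`` points; ``"mc"`` averages the gain
    over seeded draws from the posterior.
    """
    a1, a2 = best_and_second(cache, state)
    is_best = action == a1
    c = cache.mean(state, a2) if is_best else cache.mean(state, a1)
    a = cache.alpha[state, action]
    b = cache.beta[state, action]
    if backend == "exact":
        return float(_vpi_exact(a, b, c, is_best))
    if backend == "grid":
        from .bayes_core import BetaDist

        x = (np.arange(nodes) + 0.5) / nodes
        g = np.maximum(c - x, 0.0) if is_best else np.maximum(x - c, 0.0)
        return float(np.sum(g * BetaDist(a, b).pdf(x)) / nodes)
    if backend == "mc":
        if rng is None:
            raise ValueError("mc backend requires an rng")
        x = rng.beta(a, b, size=nodes)
        g = np.maximum(c - x, 0.0) if is_best else np.maximum(x - c, 0.0)
        return float(g.mean())
    raise ValueError(f"unknown backend {backend!r}")


def vpi_values(cache: CacheQTable, state: int, means: np.ndarray | None = None) -> np.ndarray:
    """Exact VPI for every action of a state in one vectorized call.

    ``means`` may be passed to reuse an already-computed posterior-mean row.
    """
    if means is None:
        means = cache.means(state)
    order = np.argsort(-means, kind="stable")
    a1, a2 = int(order[0]), int(order[1])
    n = cache.n_actions
    is_best = np.zeros(n, dtype=bool)
    is_best[a1] = True
    c = np.full(n, means[a1])
    c[a1] = means[a2]
    return _vpi_exact(cache.alpha[state], cache.beta[state], c, is_best)


def select_system(vpi_value: float, arb: ArbitrationState) -> str:
    """Tree wins only on a strict advantage over the opportunity cost."""
    return "tree" if vpi_value > arb.threshold else "cache"


def update_avg_reward(arb: ArbitrationState, r: float) -> ArbitrationState:
    """Exponential average-reward update; a no-op in fixed (promised) mode."""
    if arb.mode == "observed":
        arb.avg_reward = (1.0 - arb.eta) * arb.avg_reward + arb.eta * r
    return arb
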