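"""Beta and Dirichlet primitives used by both controllers.

Everything the two learning systems track is either a Beta posterior over a
value/reward in [0, 1] or a Dirichlet row over successor states.  This module
provides the shared operations on those objects: moments, mean-preserving
reshaping (picking the higher-variance solution), moment-matched mixture
updates, and exponential forgetting toward stored priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "BetaDist",
    "DirichletRow",
    "beta_moments",
    "beta_from_moments",
    "clamp_mean",
    "reshape_to_mean",
    "mixture_moments",
    "mixture_update",
    "decay_toward_prior",
    "dirichlet_mean",
    "MEAN_FLOOR",
    "MEAN_CEIL",
    "PARAM_FLOOR",
]

# Target means are clamped into this range before any reshaping so that
# cost/discount-shifted targets stay inside the open unit interval.
MEAN_FLOOR = 1e-3
MEAN_CEIL = 0.999

# Moment matching can request a variance too large for its mean; parameters
# are floored here to keep distributions proper.
PARAM_FLOOR = 1e-3


@dataclass(frozen=True)
class BetaDist:
    """A Beta distribution with strictly positive pseudo-counts."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("Beta parameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"Beta parameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    @property
    def second_moment(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * (self.alpha + 1.0) / (s * (s + 1.0))

    def pdf(self, x):
        """Density, evaluated via the log-Beta function for stability."""
        x = np.asarray(x, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = (
                (self.alpha - 1.0) * np.log(x)
                + (self.beta - 1.0) * np.log1p(-x)
                - special.betaln(self.alpha, self.beta)
            )
        out = np.exp(logp)
        return np.where((x < 0) | (x > 1), 0.0, out)


@dataclass(frozen=True)
class DirichletRow:
    """Dirichlet concentrations over successor states for one (state, action)."""

    concentration: np.ndarray

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentration, dtype=float)
        if conc.ndim != 1 or conc.size == 0:
            raise ValueError("concentration must be a non-empty vector")
        if not np.all(np.isfinite(conc)) or np.any(conc <= 0):
            raise ValueError("concentration entries must be positive and finite")
        object.__setattr__(self, "concentration", conc)

    @property
    def mean(self) -> np.ndarray:
        return self.concentration / self.concentration.sum()


def beta_moments(d: BetaDist) -> tuple[float, float]:
    """Closed-form (mean, variance) of a Beta distribution."""
    return d.mean, d.variance


def clamp_mean(x: float, lo: float = MEAN_FLOOR, hi: float = MEAN_CEIL) -> float:
    """Clamp a target mean into the usable open-interval range."""
    return min(max(float(x), lo), hi)


def _reshape_params(alpha: float, beta: float, target_mean: float) -> tuple[float, float]:
    """Scalar core of :func:`reshape_to_mean`; returns the chosen (alpha, beta).

    Both candidates keep one parameter of the base distribution fixed and solve
    alpha/mean = beta/(1 - mean) for the other; the candidate with the larger
    variance wins (every reshaping step should add uncertainty, not remove it).
    """
    m = target_mean
    # candidate A: keep alpha, solve for beta
    a1, b1 = alpha, alpha * (1.0 - m) / m
    # candidate B: keep beta, solve for alpha
    a2, b2 = beta * m / (1.0 - m), beta
    s1 = a1 + b1
    s2 = a2 + b2
    v1 = a1 * b1 / (s1 * s1 * (s1 + 1.0))
    v2 = a2 * b2 / (s2 * s2 * (s2 + 1.0))
    return (a1, b1) if v1 >= v2 else (a2, b2)


def reshape_to_mean(base: BetaDist, target_mean: float) -> BetaDist:
    """Return a Beta with mean ``target_mean`` derived from ``base``.

    Of the two single-parameter solutions the one with the larger variance is
    returned.  ``target_mean`` must lie strictly inside (0, 1); callers clamp
    with :func:`clamp_mean` first.
    """
    if not math.isfinite(target_mean) or not (0.0 < target_mean < 1.0):
        raise ValueError(f"target_mean must be in (0, 1), got {target_mean!r}")
    a, b = _reshape_params(base.alpha, base.beta, float(target_mean))
    return BetaDist(a, b)


def beta_from_moments(mean: float, variance: float) -> BetaDist:
    """Moment-match (mean, variance) to a Beta, flooring impossible parameters."""
    if not (0.0 < mean < 1.0):
        mean = clamp_mean(mean)
    if variance <= 0.0:
        raise ValueError(f"variance must be positive, got {variance!r}")
    nu = mean * (1.0 - mean) / variance - 1.0
    a = mean * nu
    b = (1.0 - mean) * nu
    return BetaDist(max(a, PARAM_FLOOR), max(b, PARAM_FLOOR))


def mixture_moments(
    alpha: float, beta: float, target_mean: float, target_second_moment: float
) -> tuple[float, float]:
    """Mean and variance of the Beta mixture used for cache updates.

    The mixture is  ``int Beta(alpha + x, beta + (1 - x)) t(x) dx``  over the
    target distribution ``t``.  Because every component shares the same total
    pseudo-count ``alpha + beta + 1``, the mixture moments depend on ``t`` only
    through its first two moments, which makes them available in closed form:

    mean  = (alpha + E[x]) / s                     with s = alpha + beta + 1
    E[y^2] = (alpha^2 + (2 alpha + 1) E[x] + E[x^2] + alpha) / (s (s + 1))
    """
    s = alpha + beta + 1.0
    m1 = target_mean
    m2 = target_second_moment
    mean = (alpha + m1) / s
    ey2 = (alpha * alpha + (2.0 * alpha + 1.0) * m1 + m2 + alpha) / (s * (s + 1.0))
    var = ey2 - mean * mean
    return mean, var


def mixture_update(prior: BetaDist, target: BetaDist) -> BetaDist:
    """Moment-matched posterior after mixing ``prior`` against ``target``.

    Each possible target value x contributes a fractional Bernoulli update
    Beta(alpha + x, beta + 1 - x); the result is the target-weighted mixture
    collapsed back to a Beta by matching its first two moments.
    """
    mean, var = mixture_moments(
        prior.alpha, prior.beta, target.mean, target.second_moment
    )
    if not (math.isfinite(mean) and math.isfinite(var)) or var <= 0.0:
        raise ArithmeticError(
            f"degenerate mixture moments (mean={mean!r}, var={var!r}) for "
            f"prior=({prior.alpha}, {prior.beta}), target=({target.alpha}, {target.beta})"
        )
    return beta_from_moments(mean, var)


def decay_toward_prior(current, prior, theta: float):
    """Exponential forgetting: p <- theta * p + (1 - theta) * p_prior.

    Works elementwise on scalars or arrays of matching shape.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta!r}")
    cur = np.asarray(current, dtype=float)
    pri = np.asarray(prior, dtype=float)
    if cur.shape != pri.shape:
        raise ValueError("current and prior must have identical shapes")
    return theta * cur + (1.0 - theta) * pri


def dirichlet_mean(row: DirichletRow) -> np.ndarray:
    """Normalized concentration vector (sums to one)."""
    return row.mean
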