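"""Reviewing-intensity schedules and exact next-review sampling.

Three reviewing policies are implemented as intensity functions of the
memory state:

* MEMORIZE -- the optimal policy under the quadratic loss,
  ``u(t) = q**-0.5 * (1 - m(t))``: review intensity is an affine function
  of the recall probability with slope ``-q**-0.5``.  No reviews are
  proposed while recall is certain, and the intensity saturates at
  ``q**-0.5`` as the item is forgotten.
* uniform -- a state-independent constant rate ``mu`` (homogeneous Poisson).
* threshold -- the classical "review when about to forget" heuristic: the
  intensity is 0 until the recall probability crosses ``m_th`` downward at
  time ``s``, then grows as ``c * exp((t - s) / zeta)``.

Next review times are drawn exactly by thinning an inhomogeneous Poisson
process: candidate times are proposed from a dominating piecewise-constant
bound and accepted with probability ``u(t)/bound``.  MEMORIZE and uniform
have global bounds; the threshold intensity is unbounded, so its bound
schedule uses adaptive look-ahead windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np

from .memory import ExponentialForgettingModel, MemoryState

__all__ = [
    "MemorizeScheduler",
    "UniformScheduler",
    "ThresholdScheduler",
    "SchedulerSpec",
    "memorize_intensity",
    "uniform_intensity",
    "threshold_crossing_time",
    "threshold_intensity",
    "sample_next_event",
]


def memorize_intensity(m: float, q: float) -> float:
    """Optimal reviewing intensity u = q**-0.5 * (1 - m)."""
    if q <= 0:
        raise ValueError(f"q must be > 0, got {q}")
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"m must be in [0, 1], got {m}")
    return (1.0 - m) / math.sqrt(q)


def uniform_intensity(mu: float) -> float:
    """Constant reviewing intensity mu (1/day)."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    return mu


def threshold_crossing_time(state: MemoryState, m_th: float) -> float:
    """Time at which m(t) = m_th, i.e. t_last - ln(m_th)/n.

    Returns ``inf`` ("never") for n = 0.
    """
    if not 0.0 < m_th < 1.0:
        raise ValueError(f"m_th must be in (0, 1), got {m_th}")
    if state.n == 0.0:
        return math.inf
    return state.t_last - math.log(m_th) / state.n


def threshold_intensity(t: float, s: float, c: float, zeta: float) -> float:
    """Threshold-schedule intensity: 0 before the crossing time s, then
    c * exp((t - s)/zeta)."""
    if zeta <= 0:
        raise ValueError(f"zeta must be > 0, got {zeta}")
    if c < 0:
        raise ValueError(f"c must be >= 0, got {c}")
    if not math.isfinite(s) or t < s:
        return 0.0
    return c * math.exp((t - s) / zeta)


@dataclass(frozen=True)
class MemorizeScheduler:
    """MEMORIZE policy with review-cost tradeoff q > 0."""

    q: float
    variant = "memorize"

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError(f"q must be > 0, got {self.q}")

    def intensity(self, state: MemoryState, t: float,
                  model: Optional[ExponentialForgettingModel] = None) -> float:
        model = model or _EXP
        return memorize_intensity(model.recall_probability(state, t), self.q)

    def bound(self, state: MemoryState, t: float) -> tuple[float, float]:
        # 1 - m <= 1, globally
        return 1.0 / math.sqrt(self.q), math.inf


@dataclass(frozen=True)
class UniformScheduler:
    """Constant-rate policy with intensity mu >= 0 (1/day)."""

    mu: float
    variant = "uniform"

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")

    def intensity(self, state: MemoryState, t: float,
                  model: Optional[ExponentialForgettingModel] = None) -> float:
        return self.mu

    def bound(self, state: MemoryState, t: float) -> tuple[float, float]:
        return self.mu, math.inf


@dataclass(frozen=True)
class ThresholdScheduler:
    """Threshold policy: intensity c*exp((t-s)/zeta) once m crosses m_th.

    After each review the recall probability jumps back to 1, so the
    threshold must be re-crossed before the intensity switches on again:
    the crossing time s is recomputed from the post-review state.
    ``delta_factor`` sets the thinning look-ahead window delta =
    delta_factor * zeta.
    """

    c: float
    zeta: float
    m_th: float
    delta_factor: float = 0.25
    variant = "threshold"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.zeta <= 0:
            raise ValueError(f"zeta must be > 0, got {self.zeta}")
        if not 0.0 < self.m_th < 1.0:
            raise ValueError(f"m_th must be in (0, 1), got {self.m_th}")

    def crossing_time(self, state: MemoryState) -> float:
        return threshold_crossing_time(state, self.m_th)

    def intensity(self, state: MemoryState, t: float,
                  model: Optional[ExponentialForgettingModel] = None) -> float:
        return threshold_intensity(t, self.crossing_time(state), self.c, self.zeta)

    def bound(self, state: MemoryState, t: float) -> tuple[float, float]:
        s = self.crossing_time(state)
        if not math.isfinite(s):
            return 0.0, math.inf
        if t < s:
            return 0.0, s
        delta = self.delta_factor * self.zeta
        return self.c * math.exp((t + delta - s) / self.zeta), t + delta


@dataclass(frozen=True)
class CramScheduler:
    """Massed practice: constant rate mu_burst until t_split, then mu_tail.

    A two-phase homogeneous Poisson policy modelling a learner who crams
    most reviews right after first exposure and rarely returns.  Used as a
    non-conformant contrast to spaced schedules.
    """

    mu_burst: float
    mu_tail: float
    t_split: float
    variant = "crammed"

    def __post_init__(self) -> None:
        if self.mu_burst < 0 or self.mu_tail < 0:
            raise ValueError("rates must be >= 0")
        if self.t_split <= 0:
            raise ValueError(f"t_split must be > 0, got {self.t_split}")

    def intensity(self, state: MemoryState, t: float,
                  model: Optional[ExponentialForgettingModel] = None) -> float:
        return self.mu_burst if t < self.t_split else self.mu_tail

    def bound(self, state: MemoryState, t: float) -> tuple[float, float]:
        if t < self.t_split:
            return self.mu_burst, self.t_split
        return self.mu_tail, math.inf


SchedulerSpec = Union[
    MemorizeScheduler, UniformScheduler, ThresholdScheduler, CramScheduler
]


def sample_next_event(
    intensity: Callable[[float], float],
    bound: Callable[[float], tuple[float, float]],
    t_now: float,
    t_f: float,
    rng: np.random.Generator,
) -> Optional[float]:
    """First event time of an inhomogeneous Poisson process on (t_now, t_f].

    ``intensity(t)`` is the target rate u(t); ``bound(t)`` returns
    ``(B, t_valid)`` such that u(s) <= B for all s in [t, t_valid)
    (piecewise-constant majorant).  Sampling is by thinning and is
    distributionally exact.  Returns None if no event occurs before ``t_f``.
    A proposal where u exceeds the bound raises RuntimeError rather than
    silently producing a biased sample.
    """
    t = t_now
    while t < t_f:
        B, t_valid = bound(t)
        t_valid = min(t_valid, t_f)
        if B <= 0.0:
            if not math.isfinite(t_valid):
                return None
            t = t_valid
            continue
        gap = rng.exponential(1.0 / B)
        if t + gap >= t_valid:
            t = t_valid
            continue
        t = t + gap
        u = intensity(t)
        if u > B * (1.0 + 1e-12):
            raise RuntimeError(
                f"thinning bound violated: u({t})={u} > bound {B}"
            )
        if rng.random() * B < u:
            return t
    return None


_EXP = ExponentialForgettingModel()
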