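"""Memory models for spaced repetition.

The central object is the exponential forgetting curve with multiplicative
rate jumps at reviews: a learner's probability of recalling an item decays as

    m(t) = exp(-n(t) * (t - t_r)),

where ``t_r`` is the time of the last review and ``n(t)`` is the forgetting
rate (1/day).  Each review is a marked point-process event with a binary
recall outcome ``r``; a successful recall multiplies the forgetting rate by
``(1 - alpha)`` and an unsuccessful one by ``(1 + beta)``, the half-life
regression jump rule.  The initial rate ``n0`` encodes item difficulty.

States are immutable values: :func:`apply_review` returns a new
:class:`MemoryState` so that simulators and estimators can replay histories
deterministically.

Two variants of the decay law are provided behind the same two-method
interface (``recall_probability`` / ``apply_review``):

* :class:`ExponentialForgettingModel` -- the default model above;
* :class:`PowerLawForgettingModel` -- heavier-tailed decay
  ``m(t) = (1 + omega * (t - t_r)) ** (-n(t))`` with the same jump rule;
* :class:`SpacingSensitiveModel` -- an exponential-decay variant in which a
  successful recall at recall probability ``m`` multiplies the rate by
  ``1 - alpha * (1 - m)``: easy (massed) reviews barely strengthen memory
  while difficult (well-spaced) ones give the full benefit.  This encodes
  the desirable-difficulty/spacing effect that the constant-``alpha`` model
  deliberately omits, and drives the conformance study in
  :mod:`memorize.studies`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "ItemParams",
    "MemoryState",
    "ReviewEvent",
    "ReviewSequence",
    "ExponentialForgettingModel",
    "PowerLawForgettingModel",
    "SpacingSensitiveModel",
    "recall_probability",
    "apply_review",
    "instantaneous_loss",
]


@dataclass(frozen=True)
class ItemParams:
    """Per-item memory parameters.

    alpha : success multiplier deficit, 0 <= alpha <= 1 (rate becomes
        ``(1-alpha)*n`` after a successful recall).
    beta : failure multiplier excess, beta >= 0 (rate becomes
        ``(1+beta)*n`` after an unsuccessful recall).
    n0 : initial forgetting rate in 1/day; larger means harder.
    """

    alpha: float
    beta: float
    n0: float
    item_id: str = "item"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n0 < 0.0:
            raise ValueError(f"n0 must be >= 0, got {self.n0}")


@dataclass(frozen=True)
class MemoryState:
    """Forgetting-rate state of one (learner, item) pair.

    ``t_last`` is the time of the last review in days, or the exposure time
    for a never-reviewed pair (``reviewed`` False).  Time is continuous with
    t = 0 at first exposure.
    """

    n: float
    t_last: float = 0.0
    k_success: int = 0
    k_fail: int = 0
    reviewed: bool = False

    def __post_init__(self) -> None:
        if self.n < 0.0:
            raise ValueError(f"forgetting rate must be >= 0, got {self.n}")
        if self.k_success < 0 or self.k_fail < 0:
            raise ValueError("recall counts must be nonnegative")

    @classmethod
    def initial(cls, params: ItemParams, t0: float = 0.0) -> "MemoryState":
        return cls(n=params.n0, t_last=t0)


@dataclass(frozen=True)
class ReviewEvent:
    """One review of an item: time (days) and binary recall outcome."""

    item_id: str
    t: float
    r: int

    def __post_init__(self) -> None:
        if self.r not in (0, 1):
            raise ValueError(f"recall outcome must be 0 or 1, got {self.r}")
        if not math.isfinite(self.t):
            raise ValueError("event time must be finite")


@dataclass(frozen=True)
class ReviewSequence:
    """Time-ordered reviews of one (learner, item) pair.

    The realization of the pair's counting process N(t).
    """

    learner_id: str
    item_id: str
    events: tuple[ReviewEvent, ...] = ()

    def __post_init__(self) -> None:
        times = [e.t for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(
                f"review times of ({self.learner_id}, {self.item_id}) "
                "must be strictly increasing"
            )
        if any(e.item_id != self.item_id for e in self.events):
            raise ValueError("all events must share the sequence's item_id")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(e.t for e in self.events)


class ExponentialForgettingModel:
    """Exponential forgetting curve with multiplicative rate jumps."""

    def recall_probability(self, state: MemoryState, t: float) -> float:
        """P(recall at time t) = exp(-n * (t - t_last)).

        Raises ValueError if ``t`` precedes the last review. ``n = 0`` is the
        degenerate permanently-remembered state with m = 1 everywhere.
        """
        dt = t - state.t_last
        if dt < 0:
            raise ValueError(
                f"t={t} precedes the last review at t_last={state.t_last}"
            )
        if state.n == 0.0:
            return 1.0
        return math.exp(-state.n * dt)

    def _success_multiplier(self, params: ItemParams, m: float) -> float:
        return 1.0 - params.alpha

    def apply_review(
        self, state: MemoryState, params: ItemParams, t: float, r: int
    ) -> MemoryState:
        """Return the post-review state; the input state is unmodified.

        Success: n -> (1-alpha) n.  Failure: n -> (1+beta) n.  The recall
        probability jumps back to 1 because ``t_last`` resets to ``t``.
        """
        if r not in (0, 1):
            raise ValueError(f"recall outcome must be 0 or 1, got {r}")
        if t < state.t_last:
            raise ValueError(
                f"review time {t} precedes last review {state.t_last}"
            )
        if r == 1:
            m = self.recall_probability(state, t)
            n_new = state.n * self._success_multiplier(params, m)
            return replace(
                state,
                n=n_new,
                t_last=t,
                k_success=state.k_success + 1,
                reviewed=True,
            )
        return replace(
            state,
            n=state.n * (1.0 + params.beta),
            t_last=t,
            k_fail=state.k_fail + 1,
            reviewed=True,
        )


class SpacingSensitiveModel(ExponentialForgettingModel):
    """Exponential decay with a desirable-difficulty success rule.

    A successful recall at recall probability ``m`` multiplies the
    forgetting rate by ``1 - alpha*(1 - m)``: reviewing an item that was
    about to be forgotten (m near 0) strengthens it by the full factor
    ``1 - alpha``, while re-reviewing immediately (m near 1) leaves the rate
    essentially unchanged.  Failures behave as in the base model.
    """

    def _success_multiplier(self, params: ItemParams, m: float) -> float:
        return 1.0 - params.alpha * (1.0 - m)


class PowerLawForgettingModel:
    """Power-law forgetting curve m(t) = (1 + omega*(t-t_r))^(-n(t)).

    Same multiplicative jump rule as the exponential model; ``omega`` (1/day)
    sets the time scale of the heavy-tailed decay.
    """

    def __init__(self, omega: float = 1.0) -> None:
        if omega <= 0:
            raise ValueError(f"omega must be > 0, got {omega}")
        self.omega = omega

    def recall_probability(self, state: MemoryState, t: float) -> float:
        dt = t - state.t_last
        if dt < 0:
            raise ValueError(
                f"t={t} precedes the last review at t_last={state.t_last}"
            )
        if state.n == 0.0:
            return 1.0
        return (1.0 + self.omega * dt) ** (-state.n)

    def apply_review(
        self, state: MemoryState, params: ItemParams, t: float, r: int
    ) -> MemoryState:
        if r not in (0, 1):
            raise ValueError(f"recall outcome must be 0 or 1, got {r}")
        if t < state.t_last:
            raise ValueError(
                f"review time {t} precedes last review {state.t_last}"
            )
        mult = (1.0 - params.alpha) if r == 1 else (1.0 + params.beta)
        counts = (
            {"k_success": state.k_success + 1}
            if r == 1
            else {"k_fail": state.k_fail + 1}
        )
        return replace(state, n=state.n * mult, t_last=t, reviewed=True, **counts)


_DEFAULT_MODEL = ExponentialForgettingModel()


def recall_probability(state: MemoryState, t: float) -> float:
    """Module-level convenience: exponential-model recall probability."""
    return _DEFAULT_MODEL.recall_probability(state, t)


def apply_review(
    state: MemoryState, params: ItemParams, t: float, r: int
) -> MemoryState:
    """Module-level convenience: exponential-model review update."""
    return _DEFAULT_MODEL.apply_review(state, params, t, r)


def instantaneous_loss(m: float, u: float, q: float) -> float:
    """Quadratic running loss 0.5*(1-m)^2 + 0.5*q*u^2.

    ``q`` > 0 trades recall probability against reviewing effort: the larger
    q, the fewer reviews the optimal schedule takes.
    """
    if q <= 0:
        raise ValueError(f"q must be > 0, got {q}")
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"m must be in [0, 1], got {m}")
    if u < 0:
        raise ValueError(f"intensity must be >= 0, got {u}")
    return 0.5 * (1.0 - m) ** 2 + 0.5 * q * u * u
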