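"""Synthetic review-log generation.

Couples a scheduler, a memory model, and Bernoulli recall marks into an
end-to-end generator: review times are sampled exactly by thinning the
scheduler's state-dependent intensity, each review is graded from the
recall probability just before the event, and the memory state jumps
according to the outcome.

Sessions may contain several attempts: ``session_correct`` is drawn
Binomial(attempts, m(t-)) and a session counts as a successful recall mark
(r = 1) only when it is perfect, the same binarization applied to
multi-question study sessions in review logs.  With the default single
attempt this reduces to marks r ~ Bernoulli(m(t-)).

Population-scale generation derives one independent RNG stream per
(learner, item) pair from the master seed, so logs are reproducible and
order-independent.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .memory import (
    ExponentialForgettingModel,
    ItemParams,
    MemoryState,
    ReviewEvent,
    ReviewSequence,
)
from .schedulers import (
    MemorizeScheduler,
    SchedulerSpec,
    ThresholdScheduler,
    UniformScheduler,
    sample_next_event,
)

__all__ = [
    "SimulationWindow",
    "SimulatedSequence",
    "PopulationConfig",
    "simulate_sequence",
    "simulate_population",
    "calibrate_q",
    "pair_seed",
]

_EXP = ExponentialForgettingModel()


@dataclass(frozen=True)
class SimulationWindow:
    """Observation window (t0, tf] in days; t0 is the first-exposure time."""

    t0: float = 0.0
    tf: float = 30.0

    def __post_init__(self) -> None:
        if not self.tf > self.t0:
            raise ValueError(f"tf={self.tf} must exceed t0={self.t0}")

    @property
    def length(self) -> float:
        return self.tf - self.t0


@dataclass(frozen=True)
class SimulatedSequence:
    """A simulated review sequence plus its session grades and trajectory.

    ``n_before``/``m_before`` hold the forgetting rate and recall
    probability immediately before each review, so estimators and tests can
    replay the generator's internal state exactly.
    """

    sequence: ReviewSequence
    seen: tuple[int, ...]
    correct: tuple[int, ...]
    n_before: tuple[float, ...]
    m_before: tuple[float, ...]
    params: ItemParams
    scheduler: SchedulerSpec
    window: SimulationWindow

    def __len__(self) -> int:
        return len(self.sequence)


def simulate_sequence(
    params: ItemParams,
    scheduler: SchedulerSpec,
    window: SimulationWindow,
    rng: np.random.Generator,
    model: Optional[ExponentialForgettingModel] = None,
    attempts: int = 1,
    learner_id: str = "learner",
    max_events: Optional[int] = None,
) -> SimulatedSequence:
    """Simulate one (learner, item) reviewing sequence over the window.

    Review times are a realization of the scheduler's point process with
    the state-dependent intensity evaluated on the current memory state;
    marks are graded from m(t-) and the state jumps via ``apply_review``.
    ``max_events`` stops the sequence after a fixed review count (stopping
    by count keeps inter-event statistics free of window truncation).
    """
    if attempts < 1:
        raise ValueError(f"attempts must be >= 1, got {attempts}")
    model = model or _EXP
    state = MemoryState.initial(params, window.t0)
    t = window.t0
    events: list[ReviewEvent] = []
    seen: list[int] = []
    correct: list[int] = []
    n_before: list[float] = []
    m_before: list[float] = []
    while max_events is None or len(events) < max_events:
        t_next = sample_next_event(
            lambda s: scheduler.intensity(state, s, model),
            lambda s: scheduler.bound(state, s),
            t,
            window.tf,
            rng,
        )
        if t_next is None:
            break
        t = t_next
        m = model.recall_probability(state, t)
        if attempts == 1:
            n_corr = int(rng.random() < m)
        else:
            n_corr = int(rng.binomial(attempts, m))
        r = int(n_corr == attempts)
        events.append(ReviewEvent(item_id=params.item_id, t=t, r=r))
        seen.append(attempts)
        correct.append(n_corr)
        n_before.append(state.n)
        m_before.append(m)
        state = model.apply_review(state, params, t, r)
    return SimulatedSequence(
        sequence=ReviewSequence(
            learner_id=learner_id, item_id=params.item_id, events=tuple(events)
        ),
        seen=tuple(seen),
        correct=tuple(correct),
        n_before=tuple(n_before),
        m_before=tuple(m_before),
        params=params,
        scheduler=scheduler,
        window=window,
    )


def pair_seed(master_seed: int, learner_id: str, item_id: str) -> np.random.SeedSequence:
    """Deterministic, order-independent RNG stream for a (learner, item) pair."""
    return np.random.SeedSequence(
        (
            int(master_seed),
            zlib.crc32(learner_id.encode("utf-8")),
            zlib.crc32(item_id.encode("utf-8")),
        )
    )


SchedulerAssigner = Callable[[int, int], SchedulerSpec]


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of a simulated learner population.

    Stands in for a platform review log: ``n_learners`` learners each study
    the same pool of ``n_items`` items.  Item difficulties n0 are drawn
    log-normally (median ``n0_median`` day^-1, log-sd ``n0_sigma``) once per
    item and shared across learners; ``alpha``/``beta`` are global.
    ``scheduler`` is either one policy for everyone or a callable
    ``(learner_index, item_index) -> SchedulerSpec`` for mixed designs.
    """

    n_learners: int
    n_items: int
    scheduler: Union[SchedulerSpec, SchedulerAssigner]
    window: SimulationWindow = SimulationWindow(0.0, 30.0)
    n0_median: float = 0.04
    n0_sigma: float = 1.0
    alpha: float = 0.3
    beta: float = 0.2
    attempts: int = 1
    master_seed: int = 0
    spacing_sensitive: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.n0_median <= 0.0 or self.n0_sigma < 0.0:
            raise ValueError("n0 distribution needs n0_median > 0, n0_sigma >= 0")
        if self.attempts < 1:
            raise ValueError(f"attempts must be >= 1, got {self.attempts}")
        if self.n_learners < 1 or self.n_items < 1:
            raise ValueError("population needs at least one learner and item")

    def item_params(self, item_index: int) -> ItemParams:
        rng = np.random.default_rng(
            np.random.SeedSequence((int(self.master_seed), 0xA11CE, item_index))
        )
        n0 = float(rng.lognormal(math.log(self.n0_median), self.n0_sigma))
        return ItemParams(
            alpha=self.alpha, beta=self.beta, n0=n0, item_id=f"i{item_index:05d}"
        )

    def scheduler_for(self, learner_index: int, item_index: int) -> SchedulerSpec:
        if callable(self.scheduler):
            return self.scheduler(learner_index, item_index)
        return self.scheduler


def simulate_population(
    config: PopulationConfig,
    model: Optional[ExponentialForgettingModel] = None,
) -> pd.DataFrame:
    """Simulate a population review log (one row per review session).

    Returns the canonical log plus bookkeeping columns: the assigned
    scheduler label and the item's true initial forgetting rate.
    Deterministic given ``config.master_seed``.
    """
    from .memory import SpacingSensitiveModel

    if model is None:
        model = SpacingSensitiveModel() if config.spacing_sensitive else _EXP
    items = [config.item_params(j) for j in range(config.n_items)]
    rows: list[tuple] = []
    for li in range(config.n_learners):
        learner_id = f"u{li:05d}"
        for j, params in enumerate(items):
            sched = config.scheduler_for(li, j)
            rng = np.random.default_rng(
                pair_seed(config.master_seed, learner_id, params.item_id)
            )
            sim = simulate_sequence(
                params,
                sched,
                config.window,
                rng,
                model=model,
                attempts=config.attempts,
                learner_id=learner_id,
            )
            for ev, k_seen, k_corr in zip(sim.sequence.events, sim.seen, sim.correct):
                rows.append(
                    (
                        learner_id,
                        params.item_id,
                        ev.t,
                        k_seen,
                        k_corr,
                        sched.variant,
                        params.n0,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "learner_id",
            "item_id",
            "t_days",
            "session_seen",
            "session_correct",
            "scheduler",
            "n0_true",
        ],
    )


def calibrate_q(
    target_mean_reviews: float,
    params: Union[ItemParams, Callable[[np.random.Generator], ItemParams]],
    window: SimulationWindow,
    rng: np.random.Generator,
    tolerance: float = 0.05,
    n_sims: int = 400,
    model: Optional[ExponentialForgettingModel] = None,
    attempts: int = 1,
    q_bracket: tuple[float, float] = (1e-6, 1e6),
) -> float:
    """Find q such that MEMORIZE's mean review count matches a target.

    Mean review count decreases monotonically in q, so the search is a
    bisection on log q.  Each candidate q is evaluated with the same
    Monte-Carlo seed (common random numbers), making the evaluated mean a
    deterministic, monotone function of q.  Raises ValueError when the
    target is unreachable within ``q_bracket``.
    """
    if target_mean_reviews <= 0:
        raise ValueError("target mean review count must be > 0")
    seed = rng.integers(0, 2**31 - 1)

    def mean_reviews(q: float) -> float:
        local = np.random.default_rng(seed)
        total = 0
        for _ in range(n_sims):
            p = params(local) if callable(params) else params
            sim = simulate_sequence(
                p,
                MemorizeScheduler(q=q),
                window,
                local,
                model=model,
                attempts=attempts,
            )
            total += len(sim)
        return total / n_sims

    lo, hi = (math.log(q_bracket[0]), math.log(q_bracket[1]))
    m_lo, m_hi = mean_reviews(math.exp(lo)), mean_reviews(math.exp(hi))
    if not (m_hi <= target_mean_reviews <= m_lo):
        raise ValueError(
            f"target {target_mean_reviews} outside achievable review counts "
            f"[{m_hi:.3g}, {m_lo:.3g}] for q in {q_bracket}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        m_mid = mean_reviews(math.exp(mid))
        if abs(m_mid - target_mean_reviews) <= tolerance * target_mean_reviews:
            return math.exp(mid)
        if m_mid > target_mean_reviews:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    q = math.exp(0.5 * (lo + hi))
    m_final = mean_reviews(q)
    if abs(m_final - target_mean_reviews) > tolerance * target_mean_reviews:
        raise ValueError(
            f"calibration did not reach target {target_mean_reviews} "
            f"(best mean {m_final:.3g} at q={q:.3g})"
        )
    return q
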