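"""End-to-end synthetic validation studies.

Two desk-scale studies exercise the full pipeline (simulate -> fit memory
model -> fit schedulers -> evaluation records -> group statistics):

* :func:`run_retention_study` -- three scheduler arms (MEMORIZE, uniform,
  threshold) with review budgets matched by calibrating q, compared on the
  empirical forgetting rate of a held-out test review.
* :func:`run_conformance_study` -- a population in which following
  MEMORIZE causally improves retention (spacing-sensitive memory), used to
  check that the per-learner correlation between MEMORIZE log-likelihood
  and empirical forgetting rate comes out negative.

Both are deterministic given their seed and sized to run in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import HalfLifeRegression, HalfLifeRegressionResults
from .evaluation import (
    GroupComparison,
    compare_groups,
    evaluate_log,
    learner_correlation,
)
from .memory import ItemParams, SpacingSensitiveModel
from .schedulers import (
    CramScheduler,
    MemorizeScheduler,
    ThresholdScheduler,
    UniformScheduler,
)
from .simulate import (
    PopulationConfig,
    SimulationWindow,
    calibrate_q,
    pair_seed,
    simulate_population,
    simulate_sequence,
)

__all__ = [
    "RetentionStudyResult",
    "run_retention_study",
    "ConformanceStudyResult",
    "run_conformance_study",
]


@dataclass
class RetentionStudyResult:
    """Outcome of the matched-budget three-arm retention study."""

    records: pd.DataFrame
    fit: HalfLifeRegressionResults
    q: float
    mu: float
    threshold: ThresholdScheduler
    mean_reviews: dict[str, float]
    median_norm: dict[str, float]
    median_raw: dict[str, float]
    memorize_vs_uniform: GroupComparison
    memorize_vs_threshold: GroupComparison

    @property
    def budget_spread(self) -> float:
        vals = list(self.mean_reviews.values())
        return (max(vals) - min(vals)) / max(vals)


def _arm_values(records: pd.DataFrame, arm: str, column: str) -> np.ndarray:
    v = records.loc[records["scheduler"] == arm, column].to_numpy(float)
    return v[np.isfinite(v)]


def run_retention_study(
    seed: int,
    sequences_per_arm: int = 600,
    n_items: int = 60,
    window: SimulationWindow = SimulationWindow(0.0, 30.0),
    threshold: ThresholdScheduler = ThresholdScheduler(c=2.0, zeta=1.0, m_th=0.6),
    n0_median: float = 0.04,
    n0_sigma: float = 1.0,
    alpha: float = 0.3,
    beta: float = 0.2,
    budget_tolerance: float = 0.05,
    min_reviews: int = 3,
) -> RetentionStudyResult:
    """Three-arm natural-experiment analog with matched review budgets.

    The threshold arm's mean review count sets the budget; the uniform
    rate matches it exactly in expectation (mu = budget / window) and the
    MEMORIZE tradeoff q is calibrated by bisection to match it within
    ``budget_tolerance``.  Each item appears in every arm (round-robin
    assignment over learners), so item difficulty cannot confound the
    comparison.  The log is pushed through the full estimation +
    evaluation pipeline; arms are compared on the median normalized
    empirical forgetting rate with two-sided Mann-Whitney tests.
    """
    n_learners = 3 * math.ceil(sequences_per_arm / n_items)
    rng = np.random.default_rng(seed)

    # the actual shared item pool (each item appears in every arm)
    pool_config = PopulationConfig(
        n_learners=n_learners,
        n_items=n_items,
        scheduler=threshold,  # placeholder; re-created below with arms
        window=window,
        n0_median=n0_median,
        n0_sigma=n0_sigma,
        alpha=alpha,
        beta=beta,
        master_seed=seed,
    )
    items = [pool_config.item_params(j) for j in range(n_items)]

    def params_sampler(local: np.random.Generator) -> ItemParams:
        return items[int(local.integers(len(items)))]

    # budget of the threshold arm, Monte-Carlo over the actual item pool
    probe = np.random.default_rng(rng.integers(0, 2**31 - 1))
    n_probe = 20 * n_items
    budget = (
        sum(
            len(simulate_sequence(items[i % n_items], threshold, window, probe))
            for i in range(n_probe)
        )
        / n_probe
    )
    mu = budget / window.length
    q = calibrate_q(
        budget,
        params_sampler,
        window,
        rng,
        tolerance=budget_tolerance,
        n_sims=600,
    )

    arms = (
        MemorizeScheduler(q=q),
        UniformScheduler(mu=mu),
        threshold,
    )
    config = PopulationConfig(
        n_learners=n_learners,
        n_items=n_items,
        scheduler=lambda li, ij: arms[(li + ij) % 3],
        window=window,
        n0_median=n0_median,
        n0_sigma=n0_sigma,
        alpha=alpha,
        beta=beta,
        master_seed=seed,
    )
    log = simulate_population(config)

    # mean reviews per assigned pair, counting pairs with zero reviews
    pairs_per_arm = n_learners * n_items / 3
    mean_reviews = (
        log.groupby("scheduler")["t_days"].size() / pairs_per_arm
    ).to_dict()

    fit = HalfLifeRegression(log).fit()
    records = evaluate_log(log, fit, min_reviews=min_reviews)

    med_norm = {
        arm: float(np.median(_arm_values(records, arm, "n_hat_norm")))
        for arm in ("memorize", "uniform", "threshold")
    }
    med_raw = {
        arm: float(np.median(_arm_values(records, arm, "n_hat")))
        for arm in ("memorize", "uniform", "threshold")
    }
    mvu = compare_groups(
        _arm_values(records, "memorize", "n_hat_norm"),
        _arm_values(records, "uniform", "n_hat_norm"),
    )
    mvt = compare_groups(
        _arm_values(records, "memorize", "n_hat_norm"),
        _arm_values(records, "threshold", "n_hat_norm"),
    )
    return RetentionStudyResult(
        records=records,
        fit=fit,
        q=q,
        mu=mu,
        threshold=threshold,
        mean_reviews={k: float(v) for k, v in mean_reviews.items()},
        median_norm=med_norm,
        median_raw=med_raw,
        memorize_vs_uniform=mvu,
        memorize_vs_threshold=mvt,
    )


@dataclass
class ConformanceStudyResult:
    """Outcome of the per-learner MEMORIZE-conformance correlation study."""

    correlations: pd.DataFrame  # learner_id, r, n_sequences
    median_r: float
    se_r: float
    n_learners: int
    records: pd.DataFrame
    fit: HalfLifeRegressionResults


def run_conformance_study(
    seed: int,
    n_learners: int = 40,
    sequences_per_learner: int = 200,
    window: SimulationWindow = SimulationWindow(0.0, 16.0),
    q_follow: float = 0.25,
    cram: CramScheduler = CramScheduler(mu_burst=4.0, mu_tail=0.25, t_split=1.5),
    n0: float = 0.25,
    alpha: float = 0.5,
    beta: float = 0.2,
    min_sequences: int = 70,
    t_center: float = 8.0,
    t_halfwidth: float = 3.2,
    test_attempts: int = 10,
) -> ConformanceStudyResult:
    """Population where MEMORIZE-conformance drives retention.

    A spacing-versus-cramming construction.  Memory follows the
    spacing-sensitive model (a success at recall probability m multiplies
    the rate by 1 - alpha*(1-m)), so well-spaced reviews genuinely
    strengthen memory while massed ones do almost nothing.  Each sequence
    follows MEMORIZE with per-sequence probability w ~ U(0, 1) (its
    conformance) and otherwise crams: a burst of reviews right after
    exposure plus sparse later reviews.  Items share one difficulty
    ``n0`` so retention differences come from review timing, not item
    draws.  The final session of each sequence -- the held-out test that
    only feeds the empirical forgetting rate -- is a
    ``test_attempts``-question quiz graded Binomial(test_attempts, m), so
    the retention metric is graded rather than binary.  The log is run
    through the standard pipeline and, per learner with at least
    ``min_sequences`` sequences of training period t_center +/-
    t_halfwidth days, the Pearson correlation between MEMORIZE
    log-likelihood and empirical forgetting rate is computed.
    """
    model = SpacingSensitiveModel()
    memorize = MemorizeScheduler(q=q_follow)
    rows: list[tuple] = []
    for li in range(n_learners):
        learner_id = f"u{li:05d}"
        for si in range(sequences_per_learner):
            item_id = f"i{li:05d}_{si:04d}"
            rng = np.random.default_rng(pair_seed(seed, learner_id, item_id))
            params = ItemParams(alpha=alpha, beta=beta, n0=n0, item_id=item_id)
            w = rng.random()
            sched = memorize if rng.random() < w else cram
            sim = simulate_sequence(
                params, sched, window, rng, model=model, learner_id=learner_id
            )
            k = len(sim)
            for j, (ev, seen, corr) in enumerate(
                zip(sim.sequence.events, sim.seen, sim.correct)
            ):
                if j == k - 1 and test_attempts > 1:
                    # held-out test session: graded multi-question quiz
                    seen = test_attempts
                    corr = int(rng.binomial(test_attempts, sim.m_before[j]))
                rows.append(
                    (learner_id, item_id, ev.t, seen, corr, sched.variant, n0)
                )
    log = pd.DataFrame(
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
    fit = HalfLifeRegression(log).fit()
    records = evaluate_log(log, fit, min_reviews=3)
    corr = learner_correlation(
        records,
        min_sequences=min_sequences,
        t_center=t_center,
        t_halfwidth=t_halfwidth,
    )
    r = corr["r"].to_numpy(float)
    return ConformanceStudyResult(
        correlations=corr,
        median_r=float(np.median(r)) if len(r) else math.nan,
        se_r=float(np.std(r, ddof=1) / math.sqrt(len(r))) if len(r) > 1 else math.nan,
        n_learners=len(r),
        records=records,
        fit=fit,
    )
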