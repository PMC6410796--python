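"""Natural-experiment evaluation of reviewing schedules.

Given a review log and a fitted memory model, each (learner, item)
sequence is scored by how closely its *training* reviews (all but the
last) follow each candidate schedule, via the point-process
log-likelihood

    LL({t_i}) = sum_i log u(t_i) - int_0^T u(t) dt,

with the compensator integral in closed form for every schedule.  The
final review is held out as a test and yields the model-free quality
metric, the empirical forgetting rate

    n_hat = -log(m_hat(t_n)) / (t_n - t_{n-1}),

optionally normalized by the item's average initial empirical rate.
Treatment/control groups are formed per (review count, training-period
bin) cell from the top quantile of sequences by each schedule's
likelihood, skipping sequences that qualify for more than one schedule,
and compared with the Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import (
    HalfLifeRegressionResults,
    M_HAT_CLAMP,
    M_TH_GRID,
    ZETA_GRID,
    _threshold_seq_ll,
    fit_q_mle_pooled,
    fit_uniform_mle,
    fit_threshold,
    rate_trajectory,
    total_one_minus_m_integral,
)

__all__ = [
    "log_likelihood",
    "memorize_log_likelihood",
    "uniform_log_likelihood",
    "threshold_log_likelihood",
    "empirical_forgetting_rate",
    "normalize_forgetting_rate",
    "evaluate_log",
    "assign_groups",
    "GroupAssignment",
    "GroupComparison",
    "compare_groups",
    "learner_correlation",
    "DEFAULT_T_EDGES",
]

# Training-period bins in days: half-open geometric bands with upper/lower
# ratio 7/3, the same proportional width as an "8 +/- 3.2 d" band.
DEFAULT_T_EDGES = (0.0, 1.0, 7 / 3, 49 / 9, 343 / 27, 2401 / 81, math.inf)


def log_likelihood(
    times: Sequence[float],
    intensity: Callable[[float], float],
    compensator: float,
) -> float:
    """Point-process log likelihood sum_i log u(t_i) - Lambda(T).

    Returns -inf (sentinel) when the intensity vanishes at an event.
    """
    total = 0.0
    for t in times:
        u = intensity(t)
        if u <= 0.0:
            return -math.inf
        total += math.log(u)
    return total - compensator


def memorize_log_likelihood(
    times: Sequence[float],
    rates: Sequence[float],
    T: float,
    q: float,
) -> float:
    """LL of reviews under u = q**-0.5 (1 - m), exponential-model m.

    ``rates`` holds the forgetting rate on each inter-review interval
    (len(times) + 1 entries); the compensator is the closed form
    q**-0.5 * sum_j [delta_j + (exp(-n_j delta_j) - 1)/n_j].
    """
    if q <= 0:
        raise ValueError(f"q must be > 0, got {q}")
    x = 1.0 / math.sqrt(q)
    A = total_one_minus_m_integral(times, rates, T)
    total = 0.0
    bounds = [0.0, *times]
    for j, t in enumerate(times):
        n = rates[j]
        delta = t - bounds[j]
        one_m = -math.expm1(-n * delta)
        if one_m <= 0.0:
            return -math.inf
        total += math.log(x * one_m)
    return total - x * A


def uniform_log_likelihood(times: Sequence[float], T: float, mu: float) -> float:
    """LL of reviews under the constant intensity mu over (0, T]."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    k = len(times)
    if k > 0 and mu == 0.0:
        return -math.inf
    return (k * math.log(mu) if k else 0.0) - mu * T


def threshold_log_likelihood(
    times: Sequence[float],
    rates: Sequence[float],
    T: float,
    c: float,
    zeta: float,
    m_th: float,
) -> float:
    """LL under u = c exp((t-s)/zeta) after each downward crossing of m_th."""
    if c < 0 or zeta <= 0 or not 0 < m_th < 1:
        raise ValueError("need c >= 0, zeta > 0, m_th in (0, 1)")
    c_hat, profile = _threshold_seq_ll(times, rates, T, zeta, m_th)
    if not math.isfinite(profile):
        return -math.inf
    k = len(times)
    if k == 0:
        return -c * _threshold_unit_compensator(times, rates, T, zeta, m_th)
    if c == 0.0:
        return -math.inf
    I0 = k / c_hat if c_hat > 0 else math.inf
    shape = profile - k * math.log(c_hat) + k  # sum (t_i - s_i)/zeta
    return k * math.log(c) + shape - c * I0


def _threshold_unit_compensator(
    times: Sequence[float],
    rates: Sequence[float],
    T: float,
    zeta: float,
    m_th: float,
) -> float:
    """Integral of exp((t-s)/zeta) indicator terms over (0, T] (unit c)."""
    log_inv = math.log(1.0 / m_th)
    bounds = [0.0, *[t for t in times if t <= T], T]
    I0 = 0.0
    for j in range(len(bounds) - 1):
        n = rates[j]
        s = bounds[j] + (log_inv / n if n > 0 else math.inf)
        if s < bounds[j + 1]:
            I0 += zeta * (math.exp((bounds[j + 1] - s) / zeta) - 1.0)
    return I0


def empirical_forgetting_rate(
    m_hat: float, t_n: float, t_prev: float, clamp: float = M_HAT_CLAMP
) -> float:
    """Model-free forgetting-rate estimate -log(m_hat)/(t_n - t_prev).

    ``m_hat`` is the empirical recall fraction of the test session; it is
    clamped to [clamp, 1] before the logarithm, and m_hat = 1 gives 0.
    """
    if t_n <= t_prev:
        raise ValueError(
            f"test review at {t_n} must follow the previous review at {t_prev}"
        )
    m = min(max(m_hat, clamp), 1.0)
    return -math.log(m) / (t_n - t_prev) + 0.0


def normalize_forgetting_rate(n_hat: float, n_hat0: float) -> float:
    """Ratio of a sequence's empirical rate to its item's initial baseline."""
    if n_hat0 <= 0:
        raise ValueError("item baseline rate must be > 0 to normalize")
    return n_hat / n_hat0


# ---------------------------------------------------------------------------
# per-sequence evaluation records


def _iter_learner_fits(df, fit, min_reviews, zeta_grid, m_th_grid, has_label):
    """Per learner: sequences, training views, and fitted scheduler params.

    Yields (learner_id, seqs, train, q_hat, mu_hat, threshold_fit) where
    ``seqs`` holds (item_id, times, marks, rates, label, m_hat_test) per
    retained sequence and ``train`` the matching (times[:-1], rates, T)
    training views.  ``df`` must be sorted by learner, item, time.
    """
    for learner_id, learner_df in df.groupby("learner_id", sort=False):
        seqs = []
        for item_id, seq in learner_df.groupby("item_id", sort=False):
            if len(seq) < min_reviews:
                continue
            times = seq["t_days"].to_numpy(float)
            marks = (
                seq["session_correct"].to_numpy() == seq["session_seen"].to_numpy()
            ).astype(int)
            params = fit.item_params(item_id)
            rates = rate_trajectory(marks, params.alpha, params.beta, params.n0)
            label = seq["scheduler"].iloc[0] if has_label else None
            m_hat_test = (
                seq["session_correct"].iloc[-1] / seq["session_seen"].iloc[-1]
            )
            seqs.append((item_id, times, marks, rates, label, m_hat_test))
        if not seqs:
            continue
        train = [
            (times[:-1], rates, times[-2]) for (_, times, _, rates, _, _) in seqs
        ]
        try:
            q_hat = fit_q_mle_pooled(train)
        except ValueError:
            q_hat = None
        k_tot = sum(len(t) for t, _, _ in train)
        T_tot = sum(T for _, _, T in train)
        mu_hat = fit_uniform_mle(k_tot, T_tot) if T_tot > 0 else 0.0
        th_fit = fit_threshold(train, zeta_grid=zeta_grid, m_th_grid=m_th_grid)
        yield learner_id, seqs, train, q_hat, mu_hat, th_fit


def fit_schedulers(
    log: pd.DataFrame,
    fit: HalfLifeRegressionResults,
    min_reviews: int = 3,
    zeta_grid: Sequence[float] = ZETA_GRID,
    m_th_grid: Sequence[float] = M_TH_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit scheduler parameters for every learner and sequence in a log.

    Returns (per_learner, per_sequence): per-learner MLEs of the MEMORIZE
    tradeoff q, the uniform rate mu, and the grid-searched threshold m_th;
    per-sequence threshold (c, zeta) with the profile log-likelihood.
    """
    df = log.sort_values(["learner_id", "item_id", "t_days"], kind="stable")
    learners, seq_rows = [], []
    for learner_id, seqs, train, q_hat, mu_hat, th_fit in _iter_learner_fits(
        df, fit, min_reviews, zeta_grid, m_th_grid, "scheduler" in df.columns
    ):
        learners.append(
            {
                "learner_id": learner_id,
                "q": math.nan if q_hat is None else q_hat,
                "mu": mu_hat,
                "m_th": th_fit.m_th,
                "n_sequences": len(seqs),
            }
        )
        for i, (item_id, *_rest) in enumerate(seqs):
            seq_rows.append(
                {
                    "learner_id": learner_id,
                    "item_id": item_id,
                    "c": th_fit.c[i],
                    "zeta": th_fit.zeta[i],
                    "ll_threshold": th_fit.log_likelihood[i],
                }
            )
    return pd.DataFrame(learners), pd.DataFrame(seq_rows)


def evaluate_log(
    log: pd.DataFrame,
    fit: HalfLifeRegressionResults,
    min_reviews: int = 3,
    zeta_grid: Sequence[float] = ZETA_GRID,
    m_th_grid: Sequence[float] = M_TH_GRID,
    clamp: float = M_HAT_CLAMP,
) -> pd.DataFrame:
    """Build one evaluation record per (learner, item) sequence.

    For every sequence with at least ``min_reviews`` reviews, the last
    review is the held-out test and reviews e_1..e_{n-1} are the training
    set scored under each schedule.  Scheduler parameters are fitted per
    learner (q, mu, m_th) or per sequence (c, zeta) by maximum likelihood,
    as the schedules' own best explanations of the observed times; the
    memory trajectory m(.) is reconstructed from the fitted model and the
    logged recall marks.

    Returns a DataFrame with columns: learner_id, item_id, n_reviews,
    T_train, ll_memorize, ll_uniform, ll_threshold, n_hat, n_hat0_item,
    n_hat_norm (NaN when the item baseline is 0), plus ``scheduler`` when
    the log carries the generating label.
    """
    df = log.sort_values(["learner_id", "item_id", "t_days"], kind="stable")
    has_label = "scheduler" in df.columns

    # item baselines n_hat0 from every pair's first review
    first = df.groupby(["learner_id", "item_id"], sort=False).head(1)
    m1 = (first["session_correct"] / first["session_seen"]).clip(clamp, 1.0)
    n_hat01 = -np.log(m1) / first["t_days"]
    n_hat0_item = (
        pd.DataFrame({"item_id": first["item_id"], "v": n_hat01})
        .groupby("item_id")["v"]
        .mean()
    )

    records: list[dict] = []
    for learner in _iter_learner_fits(
        df, fit, min_reviews, zeta_grid, m_th_grid, has_label
    ):
        learner_id, seqs, train, q_hat, mu_hat, th_fit = learner
        for i, (item_id, times, marks, rates, label, m_hat_test) in enumerate(seqs):
            t_times, _, T_w = train[i]
            ll_m = (
                memorize_log_likelihood(t_times, rates, T_w, q_hat)
                if q_hat is not None
                else -math.inf
            )
            ll_u = uniform_log_likelihood(t_times, T_w, mu_hat)
            ll_t = th_fit.log_likelihood[i]
            n_hat = empirical_forgetting_rate(
                m_hat_test, times[-1], times[-2], clamp=clamp
            )
            base = float(n_hat0_item.loc[item_id])
            rec = {
                "learner_id": learner_id,
                "item_id": item_id,
                "n_reviews": len(times),
                "T_train": times[-2] - times[0],
                "ll_memorize": ll_m,
                "ll_uniform": ll_u,
                "ll_threshold": ll_t,
                "n_hat": n_hat,
                "n_hat0_item": base,
                "n_hat_norm": n_hat / base if base > 0 else math.nan,
            }
            if has_label:
                rec["scheduler"] = label
            records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# group assignment and comparison

_LL_COLUMNS = {
    "memorize": "ll_memorize",
    "uniform": "ll_uniform",
    "threshold": "ll_threshold",
}


@dataclass(frozen=True)
class GroupAssignment:
    """Treatment/control membership: scheduler -> row indices of records."""

    members: dict[str, tuple]
    fraction: float

    def values(self, records: pd.DataFrame, column: str, group: str) -> np.ndarray:
        return records.loc[list(self.members[group]), column].to_numpy(float)


def assign_groups(
    records: pd.DataFrame,
    fraction: float = 0.25,
    t_edges: Sequence[float] = DEFAULT_T_EDGES,
    schedulers: Sequence[str] = ("memorize", "uniform", "threshold"),
) -> GroupAssignment:
    """Top-fraction likelihood groups per (n_reviews, T-bin) cell.

    Within every cell, each schedule's group takes the ceil(fraction*N)
    records with the highest likelihood under that schedule (ties broken
    by (LL, learner_id, item_id) lexicographic order, -inf never
    selected); any record in the top set of more than one schedule is
    skipped everywhere, so the groups are disjoint.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    unknown = set(schedulers) - set(_LL_COLUMNS)
    if unknown:
        raise ValueError(f"unknown schedulers {sorted(unknown)}")
    columns = {name: _LL_COLUMNS[name] for name in schedulers}
    t_bin = pd.cut(
        records["T_train"], bins=list(t_edges), right=False, labels=False
    )
    members: dict[str, list] = {k: [] for k in columns}
    for _, cell in records.groupby([records["n_reviews"], t_bin], sort=False):
        k = math.ceil(fraction * len(cell))
        top: dict[str, set] = {}
        for name, col in columns.items():
            finite = cell[np.isfinite(cell[col])]
            order = finite.sort_values(
                by=[col, "learner_id", "item_id"],
                ascending=[False, True, True],
                kind="stable",
            )
            top[name] = set(order.index[:k])
        for name in top:
            others = set().union(*(top[o] for o in top if o != name))
            members[name].extend(sorted(top[name] - others))
    return GroupAssignment(
        members={k: tuple(v) for k, v in members.items()}, fraction=fraction
    )


@dataclass(frozen=True)
class GroupComparison:
    """Box summary and Mann-Whitney U comparison of two groups."""

    median_treatment: float
    median_control: float
    q25_treatment: float
    q75_treatment: float
    q25_control: float
    q75_control: float
    u_statistic: float
    p_value: float
    n_treatment: int
    n_control: int


def _exact_mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating group assignments.

    Handles ties (pairs contribute 1/2 to U).  Two-sided p is
    2 * min(P(U <= u), P(U >= u)) under the permutation null, capped at 1.
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_of(idx: tuple[int, ...]) -> float:
        mask = np.zeros(n + m, dtype=bool)
        mask[list(idx)] = True
        a, b = pooled[mask], pooled[~mask]
        diff = a[:, None] - b[None, :]
        return float((diff > 0).sum() + 0.5 * (diff == 0).sum())

    u_obs = u_of(tuple(range(n)))
    us = np.array(
        [u_of(c) for c in itertools.combinations(range(n + m), n)]
    )
    p_le = float((us <= u_obs + 1e-12).mean())
    p_ge = float((us >= u_obs - 1e-12).mean())
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def compare_groups(
    treatment: Sequence[float], control: Sequence[float]
) -> GroupComparison:
    """Medians, type-7 quartiles, and two-sided Mann-Whitney U test.

    Exact enumeration when the combined size is <= 12; the tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(treatment, dtype=float)
    y = np.asarray(control, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    if len(x) + len(y) <= 12:
        u, p = _exact_mwu(x, y)
    else:
        u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(u), float(p)
    return GroupComparison(
        median_treatment=float(np.median(x)),
        median_control=float(np.median(y)),
        q25_treatment=float(np.quantile(x, 0.25)),
        q75_treatment=float(np.quantile(x, 0.75)),
        q25_control=float(np.quantile(y, 0.25)),
        q75_control=float(np.quantile(y, 0.75)),
        u_statistic=u,
        p_value=p,
        n_treatment=len(x),
        n_control=len(y),
    )


def learner_correlation(
    records: pd.DataFrame,
    min_sequences: int = 70,
    t_center: float = 8.0,
    t_halfwidth: float = 3.2,
    split: float = 0.5,
    metric: str = "n_hat",
) -> pd.DataFrame:
    """Per-learner Pearson correlation between MEMORIZE LL and retention.

    Learners need at least ``min_sequences`` sequences with training
    period within ``t_center +/- t_halfwidth`` days.  For each eligible
    learner the top and bottom ``split`` fractions of those sequences by
    MEMORIZE log-likelihood are pooled (the default 0.5/0.5 uses them
    all) and r is computed between LL and the empirical forgetting rate.
    Learners with zero variance in either variate are skipped.

    Returns a DataFrame (learner_id, r, n_sequences); aggregate with
    ``df["r"].median()`` and a standard error across learners.
    """
    lo, hi = t_center - t_halfwidth, t_center + t_halfwidth
    band = records[
        (records["T_train"] >= lo)
        & (records["T_train"] <= hi)
        & np.isfinite(records["ll_memorize"])
    ]
    rows = []
    for learner_id, sub in band.groupby("learner_id", sort=False):
        if len(sub) < min_sequences:
            continue
        order = sub.sort_values(
            by=["ll_memorize", "item_id"], ascending=[False, True], kind="stable"
        )
        k = int(round(split * len(order)))
        sel = order if 2 * k >= len(order) else pd.concat([order.head(k), order.tail(k)])
        ll = sel["ll_memorize"].to_numpy(float)
        nh = sel[metric].to_numpy(float)
        if np.std(ll) == 0.0 or np.std(nh) == 0.0:
            continue
        r = float(stats.pearsonr(ll, nh).statistic)
        rows.append({"learner_id": learner_id, "r": r, "n_sequences": len(sel)})
    return pd.DataFrame(rows, columns=["learner_id", "r", "n_sequences"])
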