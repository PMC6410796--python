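"""Parameter estimation from review logs.

Two layers live here:

* memory-model fitting: :class:`HalfLifeRegression`, a least-squares
  regression of observed session recall fractions on the exponential
  forgetting curve, with one global pair (alpha, beta) of jump multipliers
  and one initial forgetting rate n0 per item (statsmodels-style
  Model.fit() -> Results);
* scheduler fitting: closed-form maximum-likelihood estimators for the
  MEMORIZE tradeoff q and the uniform rate mu, and a profile-likelihood
  grid fit for the threshold schedule's (c, zeta, m_th).

All estimators consume the canonical review log: a DataFrame with columns
``learner_id, item_id, t_days, session_seen, session_correct``.  A session
counts as a successful recall mark only when it is perfect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "estimate_empirical_recall",
    "filter_log",
    "HalfLifeRegression",
    "HalfLifeRegressionResults",
    "rate_trajectory",
    "one_minus_m_integral",
    "fit_q_mle",
    "fit_uniform_mle",
    "ThresholdFit",
    "fit_threshold",
    "ZETA_GRID",
    "M_TH_GRID",
]

M_HAT_CLAMP = 1e-4
ZETA_GRID = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
M_TH_GRID = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def estimate_empirical_recall(session_seen: int, session_correct: int) -> float:
    """Empirical recall probability of one session, correct/attempts."""
    if session_seen < 1:
        raise ValueError(f"session must have >= 1 attempt, got {session_seen}")
    if not 0 <= session_correct <= session_seen:
        raise ValueError(
            f"session_correct={session_correct} outside [0, {session_seen}]"
        )
    return session_correct / session_seen


def filter_log(
    log: pd.DataFrame,
    min_events_per_learner: int = 30,
    min_reviews_per_item: int = 30,
) -> pd.DataFrame:
    """Keep learners and items with enough reviewing events.

    Applies both thresholds repeatedly until a fixed point: removing a
    sparse learner can push an item below threshold and vice versa.
    """
    out = log
    while True:
        by_learner = out.groupby("learner_id")["t_days"].transform("size")
        by_item = out.groupby("item_id")["t_days"].transform("size")
        keep = (by_learner >= min_events_per_learner) & (
            by_item >= min_reviews_per_item
        )
        if keep.all():
            return out
        out = out[keep]
        if out.empty:
            return out


# ---------------------------------------------------------------------------
# half-life regression


def _prepare_design(log: pd.DataFrame) -> pd.DataFrame:
    """Per-review design rows: elapsed time, prior outcome counts, item index.

    The j-th review of a (learner, item) pair observes
    m_hat ~ exp(-n * dt) with dt the gap since the previous review (or since
    first exposure at t=0) and n determined by the item's n0 and the prior
    success/failure counts.
    """
    df = log.sort_values(["learner_id", "item_id", "t_days"], kind="stable")
    g = df.groupby(["learner_id", "item_id"], sort=False)
    t_prev = g["t_days"].shift(1).fillna(0.0)
    r_ser = (df["session_correct"] == df["session_seen"]).astype(int)
    keys = [df["learner_id"], df["item_id"]]
    ks = r_ser.groupby(keys).cumsum() - r_ser  # successes before this review
    prior = pd.Series(1, index=df.index).groupby(keys).cumsum() - 1
    kf = prior - ks
    m_hat = (df["session_correct"] / df["session_seen"]).clip(M_HAT_CLAMP, 1.0)
    return pd.DataFrame(
        {
            "learner_id": df["learner_id"],
            "item_id": df["item_id"],
            "dt": (df["t_days"] - t_prev).astype(float),
            "k_success": ks.astype(int),
            "k_fail": kf.astype(int),
            "m_hat": m_hat.astype(float),
            "r": r_ser.astype(int),
        }
    )


@dataclass
class HalfLifeRegressionResults:
    """Fitted memory-model parameters and fit diagnostics."""

    alpha: float
    beta: float
    n0: pd.Series  # indexed by item_id
    loss_trace: np.ndarray
    converged: bool
    n_obs: int
    n_items: int
    lam: float
    final_loss: float

    def item_params(self, item_id: str):
        from .memory import ItemParams

        return ItemParams(
            alpha=self.alpha,
            beta=self.beta,
            n0=float(self.n0.loc[item_id]),
            item_id=item_id,
        )

    def summary(self) -> str:
        n0 = self.n0.to_numpy()
        lines = [
            "Half-life regression (exponential forgetting curve)",
            "=" * 55,
            f"observations (reviews): {self.n_obs:>10d}",
            f"items:                  {self.n_items:>10d}",
            f"converged:              {str(self.converged):>10s}",
            f"final loss:             {self.final_loss:>10.6g}",
            f"L2 penalty lambda:      {self.lam:>10.3g}",
            "-" * 55,
            f"alpha (success multiplier 1-alpha): {self.alpha:10.4f}",
            f"beta  (failure multiplier 1+beta):  {self.beta:10.4f}",
            f"n0 median [q25, q75] (1/day): {np.median(n0):8.4f} "
            f"[{np.percentile(n0, 25):.4f}, {np.percentile(n0, 75):.4f}]",
            "=" * 55,
        ]
        return "\n".join(lines)


class HalfLifeRegression:
    """Least-squares fit of the jump-rate exponential forgetting model.

    Minimizes

        sum_j (m_hat_j - exp(-n_j * dt_j))**2 + lam * (a**2 + b**2)

    over a = -log(1-alpha) >= 0, b = log(1+beta) >= 0 and one log n0 per
    item, where n_j = n0_i * (1-alpha)**k_success * (1+beta)**k_fail is the
    model rate at the j-th review.  Deterministic: fixed initialization
    (a = b = 0; log n0 from each item's first observation) and a
    quasi-Newton optimizer with analytic gradients.
    """

    def __init__(self, log: pd.DataFrame, lam: float = 0.01) -> None:
        if log.empty:
            raise ValueError("cannot fit on an empty log")
        self.design = _prepare_design(log)
        self.lam = float(lam)
        self.items = pd.Index(pd.unique(self.design["item_id"]), name="item_id")

    def _arrays(self):
        d = self.design
        item_idx = self.items.get_indexer(d["item_id"])
        return (
            item_idx,
            d["dt"].to_numpy(),
            d["k_success"].to_numpy(float),
            d["k_fail"].to_numpy(float),
            d["m_hat"].to_numpy(),
        )

    def _initial_theta(self) -> np.ndarray:
        d = self.design
        first = d.groupby("item_id", sort=False).first()
        n0 = (-np.log(first["m_hat"]) / first["dt"]).clip(1e-4, 1e3)
        return np.log(n0.reindex(self.items).to_numpy())

    def fit(self, maxiter: int = 500, tol: float = 1e-8) -> HalfLifeRegressionResults:
        item_idx, dt, ks, kf, m_hat = self._arrays()
        n_items = len(self.items)
        lam = self.lam

        def unpack(x):
            return x[0], x[1], x[2:]

        def objective(x):
            a, b, theta = unpack(x)
            n = np.exp(theta[item_idx] - a * ks + b * kf)
            p = np.exp(-n * dt)
            resid = p - m_hat
            loss = float(resid @ resid + lam * (a * a + b * b))
            h = -2.0 * resid * dt * p  # dL/dn
            grad_n = h * n
            grad_theta = np.bincount(item_idx, weights=grad_n, minlength=n_items)
            grad_a = float(-(ks @ grad_n) + 2 * lam * a)
            grad_b = float((kf @ grad_n) + 2 * lam * b)
            return loss, np.concatenate(([grad_a, grad_b], grad_theta))

        x0 = np.concatenate(([0.0, 0.0], self._initial_theta()))
        trace: list[float] = [objective(x0)[0]]
        bounds = [(0.0, 10.0), (0.0, 10.0)] + [(math.log(1e-6), math.log(1e3))] * n_items
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            callback=lambda xk: trace.append(objective(xk)[0]),
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
        )
        a, b, theta = unpack(res.x)
        return HalfLifeRegressionResults(
            alpha=1.0 - math.exp(-a),
            beta=math.exp(b) - 1.0,
            n0=pd.Series(np.exp(theta), index=self.items, name="n0"),
            loss_trace=np.asarray(trace),
            converged=bool(res.success),
            n_obs=len(dt),
            n_items=n_items,
            lam=lam,
            final_loss=float(res.fun),
        )


def rate_trajectory(
    marks: Sequence[int], alpha: float, beta: float, n0: float
) -> np.ndarray:
    """Forgetting rate on each inter-review interval.

    For k reviews with outcomes ``marks``, returns k+1 rates: element j is
    the rate in force on the interval ending at review j+1 (element 0 is n0,
    before any review; element k applies after the last review).
    """
    mults = np.where(np.asarray(marks, dtype=int) == 1, 1.0 - alpha, 1.0 + beta)
    return n0 * np.concatenate(([1.0], np.cumprod(mults)))


def one_minus_m_integral(n: float, delta: float) -> float:
    """Closed form of the integral of 1 - exp(-n*t) over [0, delta]."""
    if delta < 0:
        raise ValueError(f"interval length must be >= 0, got {delta}")
    if n <= 0:
        return 0.0
    x = n * delta
    if x < 1e-8:
        # series: delta - (1-e^-x)/n ~ n d^2/2 - n^2 d^3/6
        return n * delta * delta / 2.0 - x * x * delta / 6.0
    return delta + (math.exp(-x) - 1.0) / n


def total_one_minus_m_integral(
    times: Sequence[float], rates: Sequence[float], T: float, t0: float = 0.0
) -> float:
    """Integral of 1 - m(t) over (t0, T] for a reviewed sequence.

    ``rates`` has one entry per inter-review interval (len(times) + 1,
    from :func:`rate_trajectory`); m resets to 1 at each review.
    """
    times = [t for t in times if t <= T]
    if len(rates) < len(times) + 1:
        raise ValueError("need len(times) + 1 interval rates")
    bounds = [t0, *times, T]
    total = 0.0
    for j in range(len(bounds) - 1):
        delta = bounds[j + 1] - bounds[j]
        if delta > 0:
            total += one_minus_m_integral(rates[j], delta)
    return total


def fit_q_mle(
    times: Sequence[float],
    rates: Sequence[float],
    T: Optional[float] = None,
    t0: float = 0.0,
) -> float:
    """Closed-form MLE of the MEMORIZE tradeoff q for one sequence.

    Under u(t) = q**-0.5 * (1 - m(t)) the likelihood is maximized at
    q_hat = (A / k)**2 with A the integral of 1 - m over the observation
    window and k the number of reviews.
    """
    if len(times) < 1:
        raise ValueError("need at least one review to fit q")
    if T is None:
        T = times[-1]
    A = total_one_minus_m_integral(times, rates, T, t0)
    if A <= 0:
        raise ValueError("integral of 1 - m is zero (m identically 1): q undefined")
    k = sum(1 for t in times if t <= T)
    return (A / k) ** 2


def fit_q_mle_pooled(
    sequences: Iterable[tuple[Sequence[float], Sequence[float], float]],
) -> float:
    """Pooled per-learner MLE of q over (times, rates, T) sequences.

    Maximizing the summed log-likelihood gives q_hat = (sum A / sum k)**2.
    """
    A_tot = 0.0
    k_tot = 0
    for times, rates, T in sequences:
        A_tot += total_one_minus_m_integral(times, rates, T)
        k_tot += sum(1 for t in times if t <= T)
    if k_tot == 0 or A_tot <= 0:
        raise ValueError("no reviews (or m identically 1): q undefined")
    return (A_tot / k_tot) ** 2


def fit_uniform_mle(n_events: int, T: float) -> float:
    """Homogeneous-Poisson MLE mu_hat = k / T."""
    if T <= 0:
        raise ValueError(f"window length must be > 0, got {T}")
    if n_events < 0:
        raise ValueError("event count must be >= 0")
    return n_events / T


# ---------------------------------------------------------------------------
# threshold schedule fitting


@dataclass(frozen=True)
class ThresholdFit:
    """Per-learner threshold fit: shared m_th, per-sequence (c, zeta, LL)."""

    m_th: float
    c: tuple[float, ...]
    zeta: tuple[float, ...]
    log_likelihood: tuple[float, ...]

    @property
    def total_ll(self) -> float:
        finite = [v for v in self.log_likelihood if math.isfinite(v)]
        return sum(finite) if finite else -math.inf


def _threshold_seq_ll(
    times: Sequence[float],
    rates: Sequence[float],
    T: float,
    zeta: float,
    m_th: float,
) -> tuple[float, float]:
    """(c_hat, profile LL) for one sequence at fixed (zeta, m_th).

    The intensity between reviews is 0 until the recall probability crosses
    m_th at s = t_prev + ln(1/m_th)/n, then c*exp((t-s)/zeta).  For k events
    the Poisson MLE is c_hat = k / I0 with I0 the unit-c compensator.  An
    event before its segment's crossing has intensity 0: LL = -inf.
    """
    log_inv = math.log(1.0 / m_th)
    bounds = [0.0, *times, T]
    k = len(times)
    I0 = 0.0
    shape = 0.0  # sum over events of (t_i - s_i)/zeta
    for j in range(len(bounds) - 1):
        t_prev, t_next = bounds[j], bounds[j + 1]
        n = rates[j]
        s = t_prev + (log_inv / n if n > 0 else math.inf)
        is_event = j < k
        if is_event and s >= t_next:
            return 0.0, -math.inf
        if s < t_next:
            I0 += zeta * (math.exp((t_next - s) / zeta) - 1.0)
            if is_event:
                shape += (t_next - s) / zeta
    if k == 0:
        return 0.0, 0.0  # sup over c >= 0 of -c*I0
    if I0 <= 0:
        return 0.0, -math.inf
    c_hat = k / I0
    return c_hat, k * math.log(c_hat) + shape - k


def fit_threshold(
    sequences: Sequence[tuple[Sequence[float], Sequence[float], float]],
    zeta_grid: Sequence[float] = ZETA_GRID,
    m_th_grid: Sequence[float] = M_TH_GRID,
) -> ThresholdFit:
    """Fit the threshold schedule for one learner.

    ``sequences`` holds (times, interval rates, T) triples, one per
    (learner, item) sequence.  For each candidate m_th (shared across the
    learner's sequences) every sequence picks its own (zeta, c): zeta by
    grid search, c by the closed-form Poisson MLE.  m_th maximizes the
    summed profile log-likelihood; a sequence whose events cannot be
    explained at any grid point (intensity 0 at an event everywhere)
    contributes -inf and is dropped from the sum only when every m_th is
    infeasible.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    # best (c, zeta, ll) per sequence for each m_th
    per_mth: dict[float, list[tuple[float, float, float]]] = {}
    for m_th in m_th_grid:
        fits = []
        for times, rates, T in sequences:
            best = (0.0, zeta_grid[0], -math.inf)
            for zeta in zeta_grid:
                c_hat, ll = _threshold_seq_ll(times, rates, T, zeta, m_th)
                if ll > best[2]:
                    best = (c_hat, zeta, ll)
            fits.append(best)
        per_mth[m_th] = fits

    def total(m_th: float, skip_inf: bool) -> float:
        lls = [f[2] for f in per_mth[m_th]]
        if skip_inf:
            lls = [v for v in lls if math.isfinite(v)]
            return sum(lls) if lls else -math.inf
        return -math.inf if any(not math.isfinite(v) for v in lls) else sum(lls)

    totals = {m: total(m, skip_inf=False) for m in m_th_grid}
    if all(not math.isfinite(v) for v in totals.values()):
        totals = {m: total(m, skip_inf=True) for m in m_th_grid}
    best_mth = max(m_th_grid, key=lambda m: (totals[m], m))
    fits = per_mth[best_mth]
    return ThresholdFit(
        m_th=best_mth,
        c=tuple(f[0] for f in fits),
        zeta=tuple(f[1] for f in fits),
        log_likelihood=tuple(f[2] for f in fits),
    )
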