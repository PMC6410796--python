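# Methods

## The model

A learner's memory of an item is described by the exponential forgetting
curve with review-driven jumps. Between reviews, the probability of
recalling the item at time `t` decays as

    m(t) = exp(-n(t) * (t - t_r)),

where `t_r` is the time of the last review (or of first exposure, which
defines `t = 0`) and `n(t)` is the forgetting rate in 1/day — the inverse
of the memory half-life up to a factor `ln 2`. Every review is a marked
point-process event with a binary recall mark `r`; reviews multiply the
forgetting rate:

    success (r = 1):  n -> (1 - alpha) * n        0 <= alpha <= 1
    failure (r = 0):  n -> (1 + beta)  * n        beta >= 0

and reset `m` to 1 (the jump term `(1 - m) dN` of the recall-probability
SDE `dm = -n m dt + (1 - m) dN`). The initial rate `n0` encodes item
difficulty. `alpha` and `beta` are global (shared across items); `n0` is
per item. `n = 0` is admitted as a degenerate "permanently remembered"
state with `m == 1`.

Two variant decay laws share the same interface: a power-law curve
`m(t) = (1 + omega (t - t_r))^(-n(t))` with the same jump rule, and a
*spacing-sensitive* exponential variant whose success multiplier is
`1 - alpha * (1 - m(t-))`: a review of an item that was about to be
forgotten earns the full strengthening, a massed re-review earns almost
none. The base model deliberately has constant multipliers — constant
`alpha, beta` is what half-life regression assumes — so it does *not*
encode the spacing effect; the variant exists precisely to build
populations in which spaced schedules causally outperform massed ones
(see "Validation studies" below).

## The optimal schedule

Review times form a counting process `N(t)` with intensity `u(t)`.
Scheduling is cast as stochastic control of the jump SDEs above: minimize
the expected integral of the quadratic running loss

    l(m, u) = 1/2 (1 - m)^2 + 1/2 q u^2,     q > 0,

over the reviewing window. The closed-form optimal intensity is

    u*(t) = q^(-1/2) * (1 - m(t)),

an affine function of the recall probability with slope `-q^(-1/2)`:
review rarely while memory is fresh, at rate up to `q^(-1/2)` as the item
is forgotten. `q` trades retention against effort; the expected number of
reviews is monotonically decreasing in `q`, so a desired review budget is
met by bisection on `log q` against Monte-Carlo mean counts
(`calibrate_q`, tolerance 5% by default, common random numbers across
candidate `q` so the bisected function is deterministic and monotone).
Multi-item scheduling runs one independent sampler per item with its own
`q_i`.

Baselines:

* **uniform** — constant rate `mu` (homogeneous Poisson);
* **threshold** — intensity 0 until `m` crosses `m_th` downward at time
  `s`, then `c * exp((t - s)/zeta)`. After each review `m` jumps to 1, so
  the threshold must be re-crossed; the crossing time is recomputed from
  the post-review state. (This reset is the only semantics consistent
  with "review just before forgetting".)
* **crammed** — massed practice, rate `mu_burst` until `t_split` then
  `mu_tail`; used as a non-conformant contrast in the conformance study.

## Sampling

Next review times are drawn exactly by thinning: propose from a
piecewise-constant majorant, accept with probability `u(t)/bound`.
MEMORIZE uses the global bound `q^(-1/2)` (since `m in [0, 1]`), uniform
uses `mu`; the threshold intensity is unbounded, so its majorant is the
adaptive look-ahead bound `c * exp((t + delta - s)/zeta)` on windows of
length `delta = zeta/4` (exactness is unaffected by `delta`; only
efficiency is). A proposal at which the target exceeds the bound raises
an error rather than silently biasing the draw. Sampler exactness is
verified by the time-rescaling theorem: compensator increments between
events, in closed form per schedule, must be iid Exp(1). Sequences for
these checks stop at a fixed event *count* — stopping at a fixed time and
pooling only observed gaps under-represents long gaps and visibly biases
the KS statistic at 10^4 samples.

Simulated marks: with single-attempt sessions (the default),
`r ~ Bernoulli(m(t-))`. A session may instead contain `k` attempts;
`session_correct ~ Binomial(k, m(t-))` and the session counts as a
successful recall only when perfect, the standard binarization for
multi-question sessions. `k = 1` reduces to the Bernoulli mark law.
Population logs derive one RNG stream per (learner, item) pair from the
master seed via a stable hash, so generation is deterministic and
order-independent.

## Estimation

`HalfLifeRegression` fits the memory model to a log by least squares on
session recall fractions: with `m_hat` clamped to `[1e-4, 1]`,

    minimize  sum_j (m_hat_j - exp(-n_j dt_j))^2 + lambda (a^2 + b^2)

over `a = -log(1-alpha) >= 0`, `b = log(1+beta) >= 0` and one `log n0`
per item, where `n_j = exp(log n0_i - a k_success + b k_fail)` uses the
outcome counts before review `j` and `dt_j` is the gap since the previous
review (or first exposure). The objective regresses on recall probability
only, the simplest regression consistent with the jump-rate model; the L2
penalty (`lambda = 0.01`) applies to the two global parameters, so a
single noiseless (dt, m_hat) pair still recovers `n0 = -log(m_hat)/dt`
exactly. Optimization is deterministic: fixed initialization (`a = b =
0`, `log n0` from each item's first observation), analytic gradients,
bounded quasi-Newton, at most 500 iterations, loss tolerance 1e-8;
non-convergence within the cap is flagged on the results object, not
raised (on problems with thousands of per-item parameters the global
estimates stabilize long before the strict tolerance is met).

Scheduler fits are maximum likelihood under the point-process likelihood
`LL = sum_i log u(t_i) - integral_0^T u dt`, with every compensator in
closed form:

* MEMORIZE: on an interval of length `d` with rate `n`, the integral of
  `1 - m` is `d + (e^{-n d} - 1)/n`; the per-sequence MLE is
  `q_hat = (A/k)^2` with `A` the summed integral and `k` the event count,
  and the per-learner fit pools `q_hat = (sum A / sum k)^2`.
* uniform: `mu_hat = k/T`.
* threshold: for fixed `(zeta, m_th)` the Poisson MLE is `c_hat = k/I0`
  with `I0` the unit-`c` compensator over post-crossing segments;
  `zeta` is profiled per sequence over the grid {0.5, 1, 2, 4, 8, 16} d
  and `m_th` per learner over {0.3, ..., 0.9}. An event that precedes its
  segment's crossing has intensity 0 and sends that sequence's likelihood
  to -inf; such sequences are dropped from the learner-level grid sum
  only when every grid point is infeasible.

Log filtering applies minimum event counts per learner and per item
repeatedly to a fixed point, since each removal can cascade.

## Evaluation

Each (learner, item) sequence with `n >= 3` reviews is split structurally:
reviews `e_1..e_{n-1}` are training, the `n`-th is the held-out test.
Likelihoods under each schedule are computed on the training reviews over
`(0, t_{n-1}]`, with `m(.)` reconstructed from the fitted memory model
and the logged recall marks. The quality metric is the model-free
empirical forgetting rate

    n_hat = -log(m_hat(t_n)) / (t_n - t_{n-1}),

optionally normalized by the item's baseline `n_hat_0`, the average over
learners of `-log(m_hat(t_1))/t_1`; items with zero baseline are excluded
from normalized comparisons and retain the raw metric.

Treatment/control groups are drawn per (review count, training-period
bin) cell — default bins are geometric bands with upper/lower edge ratio
7/3, the proportional width of an "8 +/- 3.2 d" band — as each schedule's
top 25% by likelihood, skipping any sequence in the top set of more than
one schedule; ties break deterministically by (LL, learner, item). Group
comparisons use the two-sided Mann-Whitney U test, exact by enumeration
of assignments (ties allowed) when the combined size is at most 12, the
tie-corrected normal approximation otherwise; box summaries use type-7
(linear-interpolation) quantiles. The per-learner analysis computes the
Pearson correlation between MEMORIZE log-likelihood and `n_hat` over a
learner's sequences with training period within 8 +/- 3.2 d, requiring at
least 70 such sequences; learners with zero variance in either variate
are skipped.

## Validation studies

**Retention study** (`run_retention_study`): three arms — MEMORIZE,
uniform, threshold `(c = 2/d, zeta = 1 d, m_th = 0.6)` — over a 30-day
window on a shared pool of 60 items with `n0 ~ LogNormal(median 0.04/d,
log-sd 1)`, `alpha = 0.3`, `beta = 0.2`, 600 sequences per arm,
round-robin assignment so every item appears in every arm. The threshold
arm's Monte-Carlo mean review count sets the budget; `mu` matches it
exactly in expectation and `q` is calibrated to it within 5%. The full
pipeline (memory fit, scheduler fits, records, arm comparison on the
median normalized `n_hat`) then runs on the pooled log.

A structural caveat, verified analytically and by simulation: under
constant multipliers the expected change in `log n` from a review at
recall probability `m` is `m log(1-alpha) + (1-m) log(1+beta)`, strictly
decreasing in `m`. At matched budgets, a policy that reviews at high `m`
(uniform reviews at state-independent times, including immediately after
a review) therefore attains a lower final forgetting rate than MEMORIZE,
which concentrates reviews where `1 - m` is large. With single-attempt
sessions the test `m_hat` is 0 or 1, so arm medians of `n_hat` are
typically exactly 0 as well. Under this generator the study consequently
does **not** reproduce the real-data ordering in which MEMORIZE beats the
uniform baseline; that ordering rests on the human spacing effect, which
the constant-(alpha, beta) model does not encode. The study is retained
as specified because it documents precisely this boundary of the model
class; the corresponding acceptance test is expected to fail and says so.

**Conformance study** (`run_conformance_study`): a spacing-vs-cramming
population in which following MEMORIZE causally drives retention. Memory
is spacing-sensitive (`alpha = 0.5`, `beta = 0.2`), items share one
difficulty (`n0 = 0.25/d`) so retention differences come from timing
alone, and each of 200 sequences per learner (40 learners, 16-day window)
follows MEMORIZE (`q = 0.25`) with per-sequence probability `w ~ U(0,1)`
and otherwise crams (burst 4/d for 1.5 d, then 0.25/d). The held-out test
session is graded as a 10-question quiz, giving a graded retention metric;
the test mark feeds nothing downstream, so dynamics are unaffected. The
per-learner correlation between MEMORIZE log-likelihood and `n_hat` is
negative (median r between about -0.12 and -0.05 across seeds). Two
forces had to be balanced in this design: heterogeneous item difficulty
induces a *positive* LL—`n_hat` coupling (hard items have low `m` at
reviews, raising both `sum log(1 - m)` and the final rate), and a binary
test mark drowns the signal; homogeneous difficulty, a strong timing
contrast, and a graded test isolate the causal channel.

## Numerical choices and degenerate inputs

* `m_hat` is clamped to `[1e-4, 1]` before any logarithm.
* `integral of (1 - e^{-n t})` uses a series expansion for `n d < 1e-8`
  to avoid cancellation; `n = 0` yields 0.
* Likelihood sentinels: an event where the intensity vanishes gives
  `LL = -inf`, never an exception; `-inf` records are excluded from
  group selection.
* Quantiles are type-7 throughout; all selection ties break by
  deterministic lexicographic keys.
* Times are serialized with six decimal places, so written logs
  round-trip byte-identically.
* Seeds: every simulation entry point takes either a `numpy` Generator or
  an integer master seed; per-pair streams come from
  `SeedSequence((master, crc32(learner), crc32(item)))`.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the model asserts —
exponential decay, multiplicative jumps, Bernoulli/Binomial session
grades, scheduler-specific event streams — and nothing else. Real review
logs additionally contain circadian and weekday structure, learner
dropout, item dependence (a review of one word strengthens related
words), session-level correlation across items, and the human spacing
effect. Passing tests on simulated data therefore certify the
implementation (formulas, samplers, estimators, pipeline plumbing), and
the conformance study certifies the evaluation machinery's ability to
detect a causal schedule effect when one exists; they do not certify that
the base model is an adequate description of human memory.

## Known limitations

* The evaluation fits and scores with the exponential model; the
  power-law variant is available but not wired into the evaluation
  pipeline.
* The threshold `zeta` is weakly identified on short sequences; its grid
  fit is reliable only with many post-crossing events per sequence.
* Group assignment assumes enough records per (n, T-bin) cell; sparse
  cells yield small or empty groups, which are reported, not imputed.
* Multi-item scheduling is independent per item by construction; no
  cross-item review budget is enforced beyond the per-item `q_i`.
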