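"""Likelihood engine, forgetting-rate metric, groups and comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from memorize.estimation import rate_trajectory
from memorize.evaluation import (
    assign_groups,
    compare_groups,
    empirical_forgetting_rate,
    learner_correlation,
    log_likelihood,
    memorize_log_likelihood,
    normalize_forgetting_rate,
    threshold_log_likelihood,
    uniform_log_likelihood,
)


class TestLogLikelihood:
    def test_uniform_closed_form(self):
        # mu = 2, events at 0.5 and 1.0, T = 2: LL = 2 log 2 - 4
        ll = uniform_log_likelihood([0.5, 1.0], 2.0, 2.0)
        assert ll == pytest.approx(2 * math.log(2) - 4.0, rel=1e-12)

    def test_no_events_is_minus_compensator(self):
        assert uniform_log_likelihood([], 3.0, 0.7) == pytest.approx(-2.1)

    def test_zero_intensity_at_event_is_minus_inf(self):
        assert uniform_log_likelihood([1.0], 2.0, 0.0) == -math.inf
        assert log_likelihood([1.0], lambda t: 0.0, 5.0) == -math.inf

    def test_constant_intensity_scaling_identity(self):
        """Scaling u = mu by gamma changes LL by k log gamma - (gamma-1) mu T."""
        times, T, mu, gamma = [0.3, 1.1, 1.9], 2.5, 0.8, 3.0
        base = uniform_log_likelihood(times, T, mu)
        scaled = uniform_log_likelihood(times, T, gamma * mu)
        expected = len(times) * math.log(gamma) - (gamma - 1) * mu * T
        assert scaled - base == pytest.approx(expected, rel=1e-12)

    def test_memorize_ll_matches_adaptive_quadrature(self):
        """Closed-form compensator vs numerical integration of u(t)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            k = int(rng.integers(1, 6))
            times = np.sort(rng.uniform(0.5, 20.0, k))
            marks = rng.integers(0, 2, k)
            n0 = float(rng.uniform(0.05, 1.0))
            rates = rate_trajectory(marks, 0.3, 0.2, n0)
            T = float(times[-1] + rng.uniform(0.1, 5.0))
            q = float(rng.uniform(0.2, 5.0))
            x = q ** -0.5
            bounds = [0.0, *times, T]

            def u(t):
                j = np.searchsorted(times, t, side="left")
                return x * (1 - math.exp(-rates[j] * (t - bounds[j])))

            comp = sum(
                quad(u, bounds[j], bounds[j + 1], limit=200)[0]
                for j in range(len(bounds) - 1)
            )
            oracle = sum(math.log(u(t)) for t in times) - comp
            ll = memorize_log_likelihood(list(times), rates, T, q)
            assert ll == pytest.approx(oracle, rel=1e-6)

    def test_threshold_ll_matches_quadrature(self):
        c, zeta, m_th, n0 = 0.8, 2.0, 0.6, 0.5
        times = [3.0, 6.0, 12.0]
        rates = rate_trajectory([1, 0, 1], 0.3, 0.2, n0)
        T = 15.0
        bounds = [0.0, *times, T]
        s_list = [
            bounds[j] + math.log(1 / m_th) / rates[j] for j in range(len(bounds) - 1)
        ]

        def u(t):
            j = np.searchsorted(times, t, side="left")
            s = s_list[j]
            return c * math.exp((t - s) / zeta) if t >= s else 0.0

        comp = sum(
            quad(u, bounds[j], bounds[j + 1], points=[s_list[j]], limit=200)[0]
            for j in range(len(bounds) - 1)
        )
        oracle = sum(math.log(u(t)) for t in times) - comp
        ll = threshold_log_likelihood(times, rates, T, c, zeta, m_th)
        assert ll == pytest.approx(oracle, rel=1e-6)


class TestEmpiricalForgettingRate:
    @pytest.mark.parametrize(
        "m_hat, t_n, t_prev, expected",
        [
            (0.5, 2.0, 0.0, math.log(2) / 2),
            (1.0, 5.0, 1.0, 0.0),
            (math.exp(-3), 1.5, 0.0, 2.0),
        ],
    )
    def test_closed_form(self, m_hat, t_n, t_prev, expected):
        assert empirical_forgetting_rate(m_hat, t_n, t_prev) == pytest.approx(
            expected, rel=1e-12, abs=1e-15
        )

    def test_zero_retention_interval_rejected(self):
        with pytest.raises(ValueError):
            empirical_forgetting_rate(0.5, 1.0, 1.0)

    def test_normalization(self):
        assert normalize_forgetting_rate(0.4, 0.2) == pytest.approx(2.0)
        assert normalize_forgetting_rate(0.31, 0.31) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            normalize_forgetting_rate(0.4, 0.0)


def _toy_records():
    """8 records in one (n, T-bin) cell with hand-set likelihoods.

    With fraction 0.25, each schedule's top set has 2 records; record 'r0'
    tops both memorize and uniform, so it must be skipped everywhere.
    """
    data = [
        # key,   ll_m, ll_u, ll_t
        ("r0", 10.0, 10.0, -5.0),
        ("r1", 9.0, -8.0, -9.0),
        ("r2", -1.0, 9.0, -9.0),
        ("r3", -2.0, -2.0, 9.0),
        ("r4", -3.0, -7.0, 8.0),
        ("r5", -9.0, -9.0, -9.0),
        ("r6", -9.5, -9.5, -9.5),
        ("r7", -9.9, -9.9, -9.9),
    ]
    return pd.DataFrame(
        {
            "learner_id": [k for k, *_ in data],
            "item_id": ["x"] * 8,
            "n_reviews": [4] * 8,
            "T_train": [5.0] * 8,
            "ll_memorize": [a for _, a, _, _ in data],
            "ll_uniform": [b for _, _, b, _ in data],
            "ll_threshold": [c for _, _, _, c in data],
            "n_hat": np.linspace(0.1, 0.8, 8),
            "n_hat_norm": np.linspace(0.1, 0.8, 8),
        }
    )


def _brute_force_groups(records, fraction=0.25):
    """Independent enumeration of the skip-overlap top-fraction rule."""
    k = math.ceil(fraction * len(records))
    tops = {}
    for name, col in [
        ("memorize", "ll_memorize"),
        ("uniform", "ll_uniform"),
        ("threshold", "ll_threshold"),
    ]:
        ranked = sorted(
            records.index,
            key=lambda i: (-records.loc[i, col], records.loc[i, "learner_id"]),
        )
        tops[name] = set(ranked[:k])
    out = {}
    for name in tops:
        others = set().union(*(tops[o] for o in tops if o != name))
        out[name] = tops[name] - others
    return out


class TestAssignGroups:
    def test_overlap_skipped_matches_enumeration(self):
        records = _toy_records()
        got = assign_groups(records, fraction=0.25)
        expected = _brute_force_groups(records)
        for name in expected:
            assert set(got.members[name]) == expected[name]
        # r0 overlaps memorize and uniform: in no group
        assert 0 not in set().union(*got.members.values())

    def test_fraction_one_single_scheduler_takes_all_records(self):
        records = _toy_records()
        got = assign_groups(records, fraction=1.0, schedulers=["memorize"])
        assert set(got.members["memorize"]) == set(records.index)

    def test_fraction_one_all_schedulers_overlaps_everywhere(self):
        records = _toy_records()
        got = assign_groups(records, fraction=1.0)
        # with fraction 1 every record tops every schedule: all overlap
        assert all(len(v) == 0 for v in got.members.values())

    def test_tied_likelihoods_break_deterministically(self):
        records = _toy_records()
        for col in ("ll_memorize", "ll_uniform", "ll_threshold"):
            records[col] = 1.0
        g1 = assign_groups(records, fraction=0.25)
        g2 = assign_groups(records, fraction=0.25)
        assert g1.members == g2.members

    def test_groups_are_disjoint_and_bounded(self):
        rng = np.random.default_rng(4)
        records = _toy_records().copy()
        for col in ("ll_memorize", "ll_uniform", "ll_threshold"):
            records[col] = rng.normal(size=8)
        got = assign_groups(records, fraction=0.25)
        all_members = list(itertools.chain.from_iterable(got.members.values()))
        assert len(all_members) == len(set(all_members))
        for v in got.members.values():
            assert len(v) <= math.ceil(0.25 * 8)


class TestCompareGroups:
    def test_exact_p_for_separated_triples(self):
        """{1,2,3} vs {4,5,6}: U = 0 and the exact two-sided p over all
        20 equally likely assignments is 2/20 = 0.1."""
        comp = compare_groups([1, 2, 3], [4, 5, 6])
        assert comp.u_statistic == 0.0
        assert comp.p_value == pytest.approx(0.1, rel=1e-12)

    def test_identical_groups_give_p_one(self):
        comp = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert comp.p_value == pytest.approx(1.0)

    def test_quartile_convention(self):
        comp = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert comp.median_treatment == pytest.approx(2.5)
        assert comp.q25_treatment == pytest.approx(1.75)
        assert comp.q75_treatment == pytest.approx(3.25)

    def test_exact_and_asymptotic_agree_on_moderate_samples(self):
        rng = np.random.default_rng(1)
        x = list(rng.normal(0, 1, 6))
        y = list(rng.normal(1, 1, 6))
        exact = compare_groups(x, y).p_value
        big = compare_groups(x * 3, y * 3).p_value  # switches to asymptotic
        assert 0 < exact <= 1 and 0 < big <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestLearnerCorrelation:
    def _records(self, pairs_by_learner):
        rows = []
        for learner, pairs in pairs_by_learner.items():
            for j, (ll, nh) in enumerate(pairs):
                rows.append(
                    {
                        "learner_id": learner,
                        "item_id": f"i{j}",
                        "n_reviews": 4,
                        "T_train": 8.0,
                        "ll_memorize": ll,
                        "n_hat": nh,
                        "n_hat_norm": nh,
                        "ll_uniform": 0.0,
                        "ll_threshold": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_perfectly_linear_pairs(self):
        recs = self._records({"u": [(1, 2), (2, 4), (3, 6)]})
        out = learner_correlation(recs, min_sequences=3)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_anti_linear_pairs(self):
        recs = self._records({"u": [(1, 6), (2, 4), (3, 2)]})
        out = learner_correlation(recs, min_sequences=3)
        assert out["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_learner_skipped(self):
        recs = self._records({"u": [(1, 5), (2, 5), (3, 5)]})
        assert learner_correlation(recs, min_sequences=3).empty

    def test_band_and_minimum_filters(self):
        recs = self._records({"u": [(1, 2), (2, 4), (3, 6)]})
        recs.loc[0, "T_train"] = 30.0  # outside the 8 +/- 3.2 band
        assert learner_correlation(recs, min_sequences=3).empty
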