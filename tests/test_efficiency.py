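"""Turnovers, workloads, inefficiency of use of OR time, and allocation."""

from datetime import date, datetime, time

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orassess import (
    AdaptationConfig,
    CaseLog,
    CaseRecord,
    allocate_ors,
    compute_turnovers,
    compute_workloads,
    inefficiency_of_use,
    pool_low_workload_services,
    randomness_check,
)
from orassess.errors import ValidationError

DAY = date(2025, 1, 6)


def _case(cid, orn, svc, h1, m1, h2, m2, day=DAY, urgent=False):
    return CaseRecord(
        case_id=cid,
        or_name=orn,
        service=svc,
        surgeon="Dr",
        enter=datetime.combine(day, time(h1, m1)),
        exit=datetime.combine(day, time(h2, m2)),
        urgent=urgent,
    )


class TestTurnovers:
    def test_simple_gap(self, config):
        log = CaseLog([_case("a", "OR 1", "S", 8, 0, 10, 0), _case("b", "OR 1", "S", 10, 30, 12, 0)])
        (t,) = compute_turnovers(log, config)
        assert t.raw_minutes == 30 and t.capped_minutes == 30
        assert t.following_case_id == "b"

    def test_long_gap_capped_at_90(self, config):
        log = CaseLog([_case("a", "OR 1", "S", 8, 0, 10, 0), _case("b", "OR 1", "S", 12, 0, 13, 0)])
        (t,) = compute_turnovers(log, config)
        assert t.raw_minutes == 120 and t.capped_minutes == 90

    def test_single_case_or_day_yields_none(self, config):
        log = CaseLog([_case("a", "OR 1", "S", 8, 0, 10, 0)])
        assert compute_turnovers(log, config) == []

    def test_cap_holds_on_fixture(self, small_log, config):
        turnovers = compute_turnovers(small_log, config)
        assert max(t.capped_minutes for t in turnovers) <= config.turnover_cap
        assert any(t.raw_minutes == 120 for t in turnovers)  # fixture's long gap


class TestWorkloads:
    def _workload(self, records, config):
        log = CaseLog(records)
        return compute_workloads(log, compute_turnovers(log, config), config)

    def test_single_elective_case(self, config):
        (w,) = self._workload([_case("a", "OR 1", "Gen", 8, 0, 11, 0)], config)
        assert w.hours == pytest.approx(3.0)

    def test_two_cases_plus_turnover(self, config):
        out = self._workload(
            [_case("a", "OR 1", "Gen", 8, 0, 10, 0), _case("b", "OR 1", "Gen", 10, 30, 12, 30)],
            config,
        )
        (w,) = out
        assert w.hours == pytest.approx(4.5)

    def test_urgent_case_contributes_nothing(self, config):
        (w,) = self._workload([_case("a", "OR 1", "Gen", 8, 0, 13, 0, urgent=True)], config)
        assert w.hours == 0.0

    def test_turnover_attributed_to_following_service(self, config):
        out = self._workload(
            [_case("a", "OR 1", "Gen", 8, 0, 10, 0), _case("b", "OR 1", "Ortho", 10, 30, 12, 30)],
            config,
        )
        by_service = {w.service: w.hours for w in out}
        assert by_service["Gen"] == pytest.approx(2.0)
        assert by_service["Ortho"] == pytest.approx(2.5)


class TestInefficiency:
    @pytest.mark.parametrize(
        "workloads, allocated, expected",
        [([6.0], 8.0, 2.0), ([9.0], 8.0, 1.5), ([8.0, 8.0], 8.0, 0.0)],
    )
    def test_worked_values(self, config, workloads, allocated, expected):
        assert inefficiency_of_use(workloads, allocated, config) == pytest.approx(expected)

    @given(
        w=st.lists(st.floats(0, 20), min_size=1, max_size=20),
        a=st.floats(0, 24),
    )
    @settings(max_examples=100, deadline=None)
    def test_decomposition(self, w, a):
        """Inefficiency = under + ratio*over, each term nonnegative; zero iff exact match."""
        cfg = AdaptationConfig()
        under = sum(max(0.0, a - x) for x in w)
        over = sum(max(0.0, x - a) for x in w)
        total = inefficiency_of_use(w, a, cfg)
        assert total == pytest.approx(under + cfg.cost_ratio * over)
        assert total >= 0
        if all(x == a for x in w):
            assert total == 0.0


class TestPooling:
    def test_strictly_below_threshold_pooled(self, config):
        daily = {
            ("A", 3): {DAY: 5.59},
            ("B", 3): {DAY: 5.60},
            ("C", 3): {DAY: 0.0},
        }
        retained, pooled = pool_low_workload_services(daily, config)
        assert ("A", 3) in pooled and ("C", 3) in pooled
        assert ("B", 3) in retained
        assert retained[("OTHER", 3)][DAY] == pytest.approx(5.59)


class TestAllocation:
    def test_zero_workload_gets_zero_ors(self, config):
        assert allocate_ors([0.0, 0.0, 0.0], config).n_ors == 0

    def test_constant_seven_hours_gets_one_or(self, config):
        # per-day costs: k=0 -> 1.5*7 = 10.5; k=1 -> 1.0; k=2 -> 9.0
        a = allocate_ors([7.0] * 5, config)
        assert a.n_ors == 1
        assert a.inefficiency == pytest.approx(5 * 1.0)

    def test_constant_two_hours_gets_zero_ors(self, config):
        # k=0 -> 1.5*2 = 3.0 beats k=1 -> 6.0
        assert allocate_ors([2.0] * 5, config).n_ors == 0

    def test_empty_workloads_error(self, config):
        with pytest.raises(ValidationError):
            allocate_ors([], config)

    def test_matches_brute_force_oracle(self, config):
        """Direct-search allocation equals exhaustive enumeration over k=0..50."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 40))
            w = list(rng.gamma(shape=2.0, scale=rng.uniform(0.5, 6.0), size=n))
            chosen = allocate_ors(w, config)
            costs = [
                inefficiency_of_use(w, k * config.staffed_hours_per_or, config)
                for k in range(51)
            ]
            best = int(np.argmin(costs))  # argmin ties -> smallest k
            assert chosen.n_ors == best
            assert chosen.inefficiency == pytest.approx(costs[best])

    def test_scaling_workload_never_decreases_allocation(self, config):
        rng = np.random.default_rng(3)
        for _ in range(20):
            w = list(rng.gamma(2.0, 3.0, size=15))
            base = allocate_ors(w, config).n_ors
            for c in (1.0, 1.3, 2.0, 4.0):
                assert allocate_ors([c * x for x in w], config).n_ors >= base

    def test_newsvendor_limit_at_fine_granularity(self):
        """As staffed hours per OR shrink, the allocation approaches the
        0.60 quantile of daily workload (the critical fractile at ratio 1.5)."""
        cfg = AdaptationConfig(staffed_hours_per_or=0.25)
        rng = np.random.default_rng(11)
        for _ in range(10):
            w = rng.gamma(6.0, 1.5, size=200)
            a = allocate_ors(list(w), cfg)
            q = float(np.quantile(w, cfg.critical_fractile))
            assert abs(a.allocated_hours - q) <= cfg.staffed_hours_per_or + 1e-9


class TestRandomnessCheck:
    def test_constant_totals_pass(self, config):
        r = randomness_check([100.0] * 9, config)
        assert r.passed and r.statistic == 0.0

    def test_strict_trend_fails(self, config):
        r = randomness_check([1, 2, 3, 4, 5, 6, 7, 8, 9], config)
        assert not r.passed
        assert r.statistic == pytest.approx(1.0)

    def test_too_few_periods_skipped(self, config):
        with pytest.warns(UserWarning, match="skipped"):
            r = randomness_check([1.0, 2.0], config)
        assert r.skipped and r.passed

    def test_type_one_error_near_alpha(self, config):
        """Stationary noise should fail at roughly the alpha = 0.01 rate."""
        rng = np.random.default_rng(0)
        fails = sum(
            not randomness_check(list(rng.normal(300, 20, size=9)), config).passed
            for _ in range(200)
        )
        assert fails / 200 <= 0.05
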