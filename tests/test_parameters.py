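"""Facility-specific scenario parameter derivation."""

import warnings
from datetime import date, datetime, time, timedelta

import pytest

from orassess import (
    Allocation,
    CaseLog,
    CaseRecord,
    build_profile,
    busiest_ors,
    first_case_counts,
    normalize_or_name,
    single_or_selection,
    workday_end,
    workday_start,
)
from orassess.errors import ParameterError
from orassess.times import ceil_to_grid, round_to_grid

THURSDAY = date(2025, 1, 9)


def _case(cid, orn, h1, m1, h2, m2, day=THURSDAY, svc="Gen", urgent=False):
    return CaseRecord(
        case_id=cid,
        or_name=orn,
        service=svc,
        surgeon="Dr",
        enter=datetime.combine(day, time(h1, m1)),
        exit=datetime.combine(day, time(h2, m2)),
        urgent=urgent,
    )


class TestNormalizeOrName:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("OR 13", "OR 13"),
            ("Rm 5", "Rm 5"),
            ("RM 2", "RM 2"),
            ("Theatre 3", "OR Theatre 3"),
            ("MAJOR 1", "MAJOR 1"),  # contains "OR" in upper case
        ],
    )
    def test_rule(self, name, expected):
        assert normalize_or_name(name) == expected

    def test_empty_name_errors(self):
        with pytest.raises(ParameterError):
            normalize_or_name("  ")


class TestBusiestOrs:
    def test_ranked_by_case_count(self):
        records = []
        for i in range(50):
            records.append(_case(f"a{i}", "OR 1", 8 + (i % 2) * 3, 0, 9 + (i % 2) * 3, 0,
                                 day=THURSDAY + timedelta(weeks=i)))
        for i in range(40):
            records.append(_case(f"b{i}", "OR 13", 8, 0, 9, 0, day=THURSDAY + timedelta(weeks=i)))
        for i in range(10):
            records.append(_case(f"c{i}", "OR 2", 8, 0, 9, 0, day=THURSDAY + timedelta(weeks=i)))
        assert busiest_ors(CaseLog(records), k=2) == ["OR 1", "OR 13"]

    def test_tie_breaks_alphabetically(self):
        records = [_case("a", "B", 8, 0, 9, 0), _case("b", "A", 10, 0, 11, 0)]
        assert busiest_ors(CaseLog(records), k=2) == ["OR A", "OR B"]

    def test_too_few_ors_errors(self):
        with pytest.raises(ParameterError):
            busiest_ors(CaseLog([_case("a", "OR 1", 8, 0, 9, 0)]), k=2)


class TestWorkdayStart:
    def test_unanimous_mode(self, config):
        records = [
            _case(f"c{i}", f"OR {i}", 7, 30, 9, 0, day=THURSDAY + timedelta(weeks=w))
            for w in range(3)
            for i in range(3)
        ]
        assert workday_start(CaseLog(records), config) == time(7, 30)

    def test_rounding_then_mode(self, config):
        # starts 07:22, 07:31, 07:29 -> rounded 07:15, 07:30, 07:30 -> mode 07:30
        records = [
            _case("a", "OR 1", 7, 22, 9, 0),
            _case("b", "OR 2", 7, 31, 9, 0),
            _case("c", "OR 3", 7, 29, 9, 0),
        ]
        assert workday_start(CaseLog(records), config) == time(7, 30)

    def test_outside_window_excluded_and_urgent_excluded(self, config):
        records = [
            _case("early", "OR 1", 6, 30, 8, 0),  # before 06:45
            _case("urgent", "OR 2", 7, 30, 9, 0, urgent=True),
            _case("ok", "OR 3", 8, 0, 9, 0),
        ]
        assert workday_start(CaseLog(records), config) == time(8, 0)

    def test_no_qualifying_cases_errors(self, config):
        monday_only = [_case("a", "OR 1", 7, 30, 9, 0, day=date(2025, 1, 6))]
        with pytest.raises(ParameterError):
            workday_start(CaseLog(monday_only), config)


class TestWorkdayEnd:
    def _staggered_day(self, ends):
        """One case per OR, all starting 08:00, ending at the given hours."""
        return [
            _case(f"c{i}", f"OR {i:02d}", 8, 0, h, m) for i, (h, m) in enumerate(ends)
        ]

    def test_round_up_behaviour(self, config):
        # median end 16:01 -> 16:15; exact grid 16:00 stays 16:00
        log_1601 = CaseLog(self._staggered_day([(14, 0), (15, 0), (16, 1), (17, 0), (18, 0)]))
        assert workday_end(log_1601, config) == time(16, 15)
        log_1600 = CaseLog(self._staggered_day([(14, 0), (15, 0), (16, 0), (17, 0), (18, 0)]))
        assert workday_end(log_1600, config) == time(16, 0)

    def test_matches_brute_force_scan(self, config):
        """Cross-check the scan rule on one constructed 10-OR Thursday."""
        ends = [(14 + i // 2, 30 * (i % 2)) for i in range(10)]  # 14:00,14:30,...18:30
        cases = self._staggered_day(ends)
        # independent enumeration: earliest exit where ORs-with-later-last-exit < 0.6*10
        exit_times = sorted(datetime.combine(THURSDAY, time(h, m)) for h, m in ends)
        expected = next(
            t for t in exit_times if sum(1 for e in exit_times if e > t) < 6
        )
        got = workday_end(CaseLog(cases), config)
        assert got == ceil_to_grid(expected.time(), config.rounding_grid)

    def test_even_date_count_takes_earlier_central_value(self, config):
        day2 = THURSDAY + timedelta(weeks=1)
        cases = self._staggered_day([(15, 0), (15, 0), (15, 0)]) + [
            _case(f"d{i}", f"OR {i:02d}", 8, 0, 17, 0, day=day2) for i in range(3)
        ]
        # per-date times: 15:00 and 17:00 -> earlier central value 15:00
        assert workday_end(CaseLog(cases), config) == time(15, 0)


class TestRounding:
    @pytest.mark.parametrize("h,m,exp", [(7, 22, (7, 15)), (7, 29, (7, 30)), (7, 37, (7, 30)),
                                         (7, 30, (7, 30)), (7, 22.5, None)])
    def test_nearest_grid(self, h, m, exp):
        if exp is None:
            # half-grid tie (7:22:30) rounds up
            assert round_to_grid(time(7, 22, 30), 15) == time(7, 30)
        else:
            assert round_to_grid(time(h, int(m)), 15) == time(*exp)

    def test_ceil_idempotent_and_fixes_grid_points(self):
        for t in (time(16, 0), time(16, 1), time(16, 14), time(23, 46)):
            once = ceil_to_grid(t, 15)
            assert ceil_to_grid(once, 15) == once
        assert round_to_grid(time(8, 45), 15) == time(8, 45)


class TestFirstCaseCounts:
    def test_median_counts_per_weekday(self, config):
        records = []
        counts = [12, 13, 14, 13]
        for w, n in enumerate(counts):
            day = THURSDAY + timedelta(weeks=w)
            for i in range(n):
                records.append(_case(f"w{w}i{i}", f"OR {i:02d}", 7, 30, 9, 0, day=day))
        out = first_case_counts(CaseLog(records), config)
        assert out[3] == 13  # lower median of {12, 13, 13, 14}

    def test_start_outside_window_contributes_nothing(self, config):
        records = [
            _case("early", "OR 1", 6, 30, 8, 0),
            _case("ok", "OR 2", 7, 0, 8, 0),
        ]
        out = first_case_counts(CaseLog(records), config)
        assert out[3] == 1


class TestSingleOrSelection:
    def _alloc(self, svc, wd, n):
        return Allocation(service=svc, weekday=wd, n_ors=n, allocated_hours=8.0 * n,
                          inefficiency=0.0, mean_workload=7.0)

    def test_earliest_qualifying_weekday_alphabetical_services(self):
        allocations = [
            self._alloc("Zeta", 0, 1),
            self._alloc("B", 3, 1),
            self._alloc("A", 3, 1),
            self._alloc("D", 3, 1),
            self._alloc("C", 3, 1),
            self._alloc("Big Service", 3, 9),
        ]
        wd, services, n_allocated = single_or_selection(allocations)
        assert wd == 3
        assert services == ["A", "B", "C"]
        assert n_allocated == 13  # 4 single-OR services + 9

    def test_no_qualifying_weekday_returns_none(self):
        allocations = [self._alloc("A", 3, 1), self._alloc("B", 3, 2)]
        assert single_or_selection(allocations) is None

    def test_other_excluded(self):
        allocations = [
            self._alloc("A", 1, 1),
            self._alloc("B", 1, 1),
            self._alloc("OTHER", 1, 1),
        ]
        assert single_or_selection(allocations) is None


class TestBuildProfile:
    def test_fixture_profile_deterministic(self, small_log):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p1 = build_profile(small_log)
            p2 = build_profile(small_log)
        assert p1.to_json() == p2.to_json()
        assert p1.busiest_ors == ["OR 1", "OR 2"]
        assert p1.holidays == {date(2025, 3, 7)}

    def test_scenario_end_late_is_end_plus_two_hours(self, sim_profile):
        end = sim_profile.workday_end
        late = sim_profile.scenario_end_late
        assert (late.hour * 60 + late.minute) - (end.hour * 60 + end.minute) == 120

    def test_derived_times_ordered(self, sim_profile):
        assert sim_profile.workday_start < sim_profile.workday_end

    def test_holiday_injection_changes_no_parameter(self, sim_log):
        """Zeroing out one weekday's cases must not move any derived parameter."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = build_profile(sim_log)
            # drop all cases on one mid-window Tuesday -> becomes an inferred holiday
            dates = sorted({r.date for r in sim_log.records if r.date.weekday() == 1})
            victim = dates[len(dates) // 2]
            pruned = sim_log.filtered(r for r in sim_log.records if r.date != victim)
            altered = build_profile(pruned)
        assert victim in altered.holidays
        assert altered.workday_start == base.workday_start
        assert altered.workday_end == base.workday_end
        assert altered.busiest_ors == base.busiest_ors
        assert altered.median_first_starts == base.median_first_starts
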