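"""Marker color derivation: the prioritization color scheme as a pure function.

The hand-frozen expectations mirror the published scheme: blue = needs an
initial visit; orange = unscheduled follow-up (black outline when already
visited today); grey = scheduled on a weekday; black = Saturday visit
scheduled or required; pink = scheduled for today; green = closed; red
outline = overdue follow-up date.
"""

import itertools
from datetime import date, timedelta

import pytest

import fieldtrack as ft
from fieldtrack import MarkerColor as C, MarkerOutline as O

from conftest import (
    FRIDAY,
    MONDAY,
    NEXT_MONDAY,
    NEXT_SATURDAY,
    SATURDAY,
    TUESDAY,
    WEDNESDAY,
    build_log,
)

TODAY = FRIDAY  # evaluation date for the example table
YESTERDAY = date(2018, 4, 5)

MISS = ("NO_ANSWER", "NO_ONE_HOME")
RECRUIT = ("CONTACT_MADE", "RECRUITED")
UNDECIDED = ("CONTACT_MADE", "UNDECIDED")


# Hand-coded expected states for the documented color-scheme cases,
# shared with the end-to-end acceptance checks.
EXAMPLE_CASES = [
    # id, visits, expected base, expected outline
    ("initial-visit", [], C.BLUE, O.NONE),
    # closed: no more visits regardless of recruitment status
    ("recruited-green", [RECRUIT + (MONDAY,)], C.GREEN, O.NONE),
    ("exhausted-green",
     [MISS + (MONDAY,), MISS + (TUESDAY,), MISS + (SATURDAY,)],
     C.GREEN, O.NONE),
    # two weekday misses, no Saturday yet: marker turns black
    ("saturday-rule-black",
     [MISS + (MONDAY,), MISS + (WEDNESDAY,)], C.BLACK, O.NONE),
    # appointment today trumps everything open
    ("scheduled-today-pink", [MISS + (MONDAY, TODAY)], C.PINK, O.NONE),
    # visited today, still open, nothing scheduled
    ("visited-today-orange-outlined",
     [MISS + (TODAY,)], C.ORANGE, O.BLACK_OUTLINE),
    ("open-orange", [MISS + (MONDAY,)], C.ORANGE, O.NONE),
    # weekday appointment missed yesterday: overdue outline
    ("overdue-grey-red", [MISS + (MONDAY, YESTERDAY)], C.GREY, O.RED_OUTLINE),
    ("future-saturday-black",
     [UNDECIDED + (MONDAY, NEXT_SATURDAY)], C.BLACK, O.NONE),
    ("future-weekday-grey",
     [UNDECIDED + (MONDAY, NEXT_MONDAY)], C.GREY, O.NONE),
]


class TestColorSchemeExamples:
    """Hand-coded expected states for the documented scheme cases."""

    @pytest.mark.parametrize(
        "visits, expected_base, expected_outline",
        [case[1:] for case in EXAMPLE_CASES],
        ids=[case[0] for case in EXAMPLE_CASES],
    )
    def test_expected_state(self, visits, expected_base, expected_outline):
        state = ft.derive_marker_state(build_log(visits), TODAY)
        assert state.base is expected_base
        assert state.outline is expected_outline

    def test_saturday_rule_black_carries_advisory(self):
        log = build_log([MISS + (MONDAY,), MISS + (WEDNESDAY,)])
        state = ft.derive_marker_state(log, TODAY)
        assert "Saturday" in state.advisory

    def test_saturday_rule_with_overdue_fu_gets_red_outline(self):
        log = build_log([MISS + (MONDAY, YESTERDAY), MISS + (WEDNESDAY,)])
        state = ft.derive_marker_state(log, TODAY)
        assert (state.base, state.outline) == (C.BLACK, O.RED_OUTLINE)


class TestRequiresSaturday:
    def test_two_weekday_misses_trigger(self):
        log = build_log([MISS + (MONDAY,), MISS + (WEDNESDAY,)])
        assert ft.requires_saturday(log)

    def test_saturday_already_visited_does_not_trigger(self):
        log = build_log([MISS + (SATURDAY,), MISS + (NEXT_MONDAY,)])
        assert not ft.requires_saturday(log)

    def test_single_miss_does_not_trigger(self):
        log = build_log([MISS + (MONDAY,)])
        assert not ft.requires_saturday(log)

    def test_disabled_by_config(self):
        config = ft.StudyConfig(saturday_required=False)
        log = build_log([MISS + (MONDAY,), MISS + (WEDNESDAY,)],
                        config=config)
        assert not ft.requires_saturday(log, config)
        assert ft.derive_marker_state(log, TODAY, config).base is C.ORANGE


class TestDailyWorklist:
    def test_pink_first_green_absent(self):
        logs = {
            "H1": build_log([MISS + (MONDAY, TODAY)], hhid="H1"),   # pink
            "H2": build_log([], hhid="H2"),                          # blue
            "H3": build_log([RECRUIT + (MONDAY,)], hhid="H3"),       # green
        }
        worklist = ft.daily_worklist(logs, TODAY)
        assert [h for h, _ in worklist] == ["H1", "H2"]

    def test_all_green_is_empty(self):
        logs = {f"H{i}": build_log([RECRUIT + (MONDAY,)], hhid=f"H{i}")
                for i in range(3)}
        assert ft.daily_worklist(logs, TODAY) == []

    def test_blue_ties_break_on_hhid(self):
        logs = {h: build_log([], hhid=h) for h in ("H9", "H2", "H5")}
        assert [h for h, _ in ft.daily_worklist(logs, TODAY)] == [
            "H2", "H5", "H9"
        ]

    def test_black_sinks_on_weekdays_rises_on_saturday(self):
        logs = {
            "HBLACK": build_log([MISS + (MONDAY,), MISS + (TUESDAY,)],
                                hhid="HBLACK"),
            "HBLUE": build_log([], hhid="HBLUE"),
        }
        weekday_order = [h for h, _ in ft.daily_worklist(logs, FRIDAY)]
        saturday_order = [h for h, _ in ft.daily_worklist(logs, SATURDAY)]
        assert weekday_order == ["HBLUE", "HBLACK"]
        assert saturday_order == ["HBLACK", "HBLUE"]

    def test_overdue_ranks_above_unscheduled(self):
        logs = {
            "HLATE": build_log([MISS + (MONDAY, YESTERDAY)], hhid="HLATE"),
            "HOPEN": build_log([MISS + (MONDAY,)], hhid="HOPEN"),
        }
        assert [h for h, _ in ft.daily_worklist(logs, TODAY)] == [
            "HLATE", "HOPEN"
        ]


def _factorial_logs():
    """Every combination of the log features the state machine reads.

    Visit counts 0-3, miss/contact pattern, Saturday visited or not,
    follow-up date in {none, past, today, future weekday, future Saturday},
    last visit today or earlier.
    """
    fu_options = (None, YESTERDAY, TODAY, NEXT_MONDAY, NEXT_SATURDAY)
    days_weekday = [MONDAY, TUESDAY, WEDNESDAY]
    for n_visits in range(4):
        patterns = itertools.product([MISS, UNDECIDED], repeat=n_visits)
        for pattern in patterns:
            for use_saturday in (False, True):
                for fu in fu_options:
                    for visited_today in (False, True):
                        days = list(days_weekday[:n_visits])
                        if use_saturday and n_visits >= 1:
                            days[0] = SATURDAY
                            days = sorted(days)
                        if visited_today and n_visits >= 1:
                            days[-1] = TODAY
                        visits = []
                        for i, (status_details, day) in enumerate(
                                zip(pattern, days)):
                            fu_here = fu if i == n_visits - 1 else None
                            visits.append(status_details + (day, fu_here))
                        yield build_log(visits)


class TestStateMachineProperties:
    def test_total_deterministic_and_single_state(self):
        """Every reachable log yields exactly one valid state, repeatably."""
        count = 0
        for log in _factorial_logs():
            first = ft.derive_marker_state(log, TODAY)
            again = ft.derive_marker_state(log, TODAY)
            assert first == again
            assert isinstance(first.base, C)
            assert isinstance(first.outline, O)
            count += 1
        assert count > 200  # the design actually spans the feature space

    def test_green_is_absorbing(self):
        """Once closed, the marker stays green on every later date."""
        closed_logs = [
            build_log([RECRUIT + (MONDAY,)]),
            build_log([MISS + (MONDAY,), MISS + (TUESDAY,),
                       MISS + (SATURDAY,)]),
            build_log([("VACANT", "EMPTY_HOME", MONDAY, NEXT_MONDAY)]),
        ]
        for log in closed_logs:
            for offset in range(0, 400, 13):
                day = TODAY + timedelta(days=offset)
                assert ft.derive_marker_state(log, day).base is C.GREEN

    def test_black_outline_only_on_orange_and_green_never_outlined(self):
        for log in _factorial_logs():
            state = ft.derive_marker_state(log, TODAY)
            if state.outline is O.BLACK_OUTLINE:
                assert state.base is C.ORANGE
            if state.base is C.GREEN:
                assert state.outline is O.NONE
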