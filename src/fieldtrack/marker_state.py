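"""Marker color derivation: the visit-tracking color scheme as a pure function.

Each household displays exactly one symbolic state derived from its log and
the current date. Base colors: BLUE never visited, ORANGE visited with an
unscheduled follow-up pending, GREY scheduled on a future weekday, BLACK
Saturday visit required or scheduled, PINK scheduled for today, GREEN
closed. Outlines modify the base: BLACK_OUTLINE marks an ORANGE household
already visited today, RED_OUTLINE marks an overdue follow-up date.

Precedence (highest first): GREEN > PINK > Saturday rule (BLACK) >
scheduled follow-up (BLACK on Saturday / GREY on weekday, RED_OUTLINE when
overdue) > ORANGE > BLUE. A household scheduled for today is PINK even when
the Saturday advisory is active: an explicit resident appointment takes
priority over everything else.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Mapping, Optional

from .config import DEFAULT_CONFIG, StudyConfig
from .model import HouseholdLog, MarkerColor, MarkerOutline, MarkerState
from .visit_engine import is_closed

SATURDAY = 6  # ISO weekday (Mon=1 .. Sun=7)

SATURDAY_ADVISORY = "next visit should be on a Saturday"


def _pending_fu_date(log: HouseholdLog) -> Optional[date]:
    """The follow-up date still awaiting its visit, if any.

    The most recently set FU_DATE is pending until a later visit occurs on
    or after that date (which consumes the appointment, kept or missed).
    """
    for idx in range(len(log.records) - 1, -1, -1):
        rec = log.records[idx]
        if rec.fu_date is None:
            continue
        consumed = any(
            later.visit_date is not None and later.visit_date >= rec.fu_date
            for later in log.records[idx + 1:]
        )
        return None if consumed else rec.fu_date
    return None


def _visited_on_saturday(log: HouseholdLog) -> bool:
    return any(
        rec.visit_date is not None and rec.visit_date.isoweekday() == SATURDAY
        for rec in log.visits
    )


def requires_saturday(
    log: HouseholdLog, config: StudyConfig = DEFAULT_CONFIG
) -> bool:
    """Whether the protocol advises the next visit fall on a Saturday.

    True once an open household has accumulated two no-contact attempts
    without any visit on a Saturday. Advisory only: recording a weekday
    visit is still permitted.
    """
    if not config.saturday_required or is_closed(log, config):
        return False
    no_contact = sum(
        1 for rec in log.visits if rec.status in config.no_contact_statuses
    )
    return no_contact >= 2 and not _visited_on_saturday(log)


def derive_marker_state(
    log: HouseholdLog,
    today: date,
    config: StudyConfig = DEFAULT_CONFIG,
) -> MarkerState:
    """Derive the unique marker state of a household for a given day.

    Total and deterministic: every valid log maps to exactly one state.
    """
    if is_closed(log, config):
        return MarkerState(MarkerColor.GREEN)

    fu = _pending_fu_date(log)
    overdue = fu is not None and fu < today
    outline = MarkerOutline.RED_OUTLINE if overdue else MarkerOutline.NONE

    if fu == today:
        return MarkerState(MarkerColor.PINK)

    if requires_saturday(log, config):
        return MarkerState(MarkerColor.BLACK, outline, SATURDAY_ADVISORY)

    if fu is not None:
        base = (MarkerColor.BLACK if fu.isoweekday() == SATURDAY
                else MarkerColor.GREY)
        return MarkerState(base, outline)

    if log.n_visits >= 1:
        visited_today = any(rec.visit_date == today for rec in log.visits)
        return MarkerState(
            MarkerColor.ORANGE,
            MarkerOutline.BLACK_OUTLINE if visited_today else MarkerOutline.NONE,
        )

    return MarkerState(MarkerColor.BLUE)


def _priority(state: MarkerState, today: date) -> int:
    if state.base is MarkerColor.PINK:
        return 0
    if state.outline is MarkerOutline.RED_OUTLINE:
        return 1
    if state.base is MarkerColor.BLACK:
        return 2 if today.isoweekday() == SATURDAY else 6
    return {MarkerColor.GREY: 3, MarkerColor.ORANGE: 4,
            MarkerColor.BLUE: 5}[state.base]


def daily_worklist(
    logs: Mapping[str, HouseholdLog] | Iterable[HouseholdLog],
    today: date,
    config: StudyConfig = DEFAULT_CONFIG,
) -> list[tuple[str, MarkerState]]:
    """Open households ordered by visit priority for one field day.

    PINK (appointments today) first, then overdue follow-ups (RED_OUTLINE),
    then BLACK Saturday households when today is a Saturday (on weekdays
    they sink to the bottom), then GREY, ORANGE, BLUE. Closed (GREEN)
    households are excluded. Ties break on HHID.
    """
    if isinstance(logs, Mapping):
        logs = logs.values()
    entries = [
        (log.hhid, derive_marker_state(log, today, config)) for log in logs
    ]
    open_entries = [
        (hhid, st) for hhid, st in entries if st.base is not MarkerColor.GREEN
    ]
    open_entries.sort(key=lambda item: (_priority(item[1], today), item[0]))
    return open_entries
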