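"""Shared fixtures: a reference calendar week and log builders.

The week of 2018-04-02 anchors date-sensitive tests: Monday 2018-04-02
through Saturday 2018-04-07, Sunday 2018-04-08.
"""

from datetime import date, datetime, time, timedelta

import pytest
from hypothesis import settings

from fieldtrack import (
    DEFAULT_CONFIG,
    HouseholdLog,
    Structure,
    record_visit,
)

# property tests explore deterministically so runs are reproducible
settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

MONDAY = date(2018, 4, 2)
TUESDAY = date(2018, 4, 3)
WEDNESDAY = date(2018, 4, 4)
FRIDAY = date(2018, 4, 6)
SATURDAY = date(2018, 4, 7)
NEXT_MONDAY = date(2018, 4, 9)
NEXT_SATURDAY = date(2018, 4, 14)


@pytest.fixture
def config():
    return DEFAULT_CONFIG


@pytest.fixture
def structure():
    return Structure(hhid="H001", cluster="CA", lat=18.01, lon=-66.61)


def build_log(
    visits=(),
    hhid="H001",
    cluster="CA",
    config=DEFAULT_CONFIG,
):
    """Build a household log through the visit engine.

    ``visits`` is a sequence of (status, details, day, fu_date) tuples;
    fu_date may be omitted.
    """
    log = HouseholdLog.from_structure(
        Structure(hhid=hhid, cluster=cluster, lat=18.0, lon=-66.6)
    )
    for i, visit in enumerate(visits):
        status, details, day = visit[:3]
        fu_date = visit[3] if len(visit) > 3 else None
        log = record_visit(
            log,
            {
                "structure": "HOUSE",
                "status": status,
                "details": details,
                "initials": "AB",
                "fu_date": fu_date,
            },
            now=datetime.combine(day, time(9, 0)) + timedelta(minutes=i),
            config=config,
        )
    return log


@pytest.fixture
def fresh_log():
    return build_log()
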