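"""Visit protocol engine: append, edit, and classify visit records.

Households are visited up to ``max_visits`` times or until a visit carries
a terminal status/detail (recruited, refused, ineligible, not a home or
vacant). All updates are pure: operations return a new log and never mutate
their input.
"""

from __future__ import annotations

from dataclasses import replace
from datetime import datetime
from typing import Mapping, Optional

from .config import DEFAULT_CONFIG, StudyConfig
from .errors import (
    ClosedHouseholdError,
    ImmutableRowError,
    NotFoundError,
    ValidationError,
)
from .model import FinalOutcome, HouseholdLog, VisitRecord

_EDITABLE_FIELDS = frozenset(
    {"structure", "status", "details", "fu_date", "fu_notes", "initials",
     "visit_datetime"}
)


def record_visit(
    log: HouseholdLog,
    entry: Mapping[str, object],
    now: datetime,
    config: StudyConfig = DEFAULT_CONFIG,
) -> HouseholdLog:
    """Append a visit attempt to an open household.

    ``entry`` supplies the user-entered fields: ``structure``, ``status``,
    ``details`` and ``initials`` are required; ``fu_date`` and ``fu_notes``
    are optional. The visit number (previous max + 1) and the timestamp
    (``now``) are auto-generated, mirroring the capture UI.

    Raises
    ------
    ClosedHouseholdError
        The household already has a final outcome or reached the visit cap.
    ValidationError
        A required field is missing or empty.
    VocabularyError
        ``details`` is not allowed for ``status``.
    """
    if is_closed(log, config):
        raise ClosedHouseholdError(
            f"{log.hhid}: closed with outcome "
            f"{final_outcome(log, config).value}"
        )
    for name in ("structure", "status", "details", "initials"):
        if not entry.get(name):
            raise ValidationError(
                f"{log.hhid}: required field {name.upper()} missing or empty"
            )
    config.validate_pair(str(entry["status"]), str(entry["details"]))
    prev = log.last
    record = VisitRecord(
        ref=prev.ref,
        hhid=log.hhid,
        cluster=log.cluster,
        lon=prev.lon,
        lat=prev.lat,
        visit=log.n_visits + 1,
        structure=str(entry["structure"]),
        status=str(entry["status"]),
        details=str(entry["details"]),
        visit_datetime=now,
        fu_date=entry.get("fu_date"),
        fu_notes=str(entry.get("fu_notes") or ""),
        initials=str(entry["initials"]),
    )
    return log.with_record(record)


def edit_visit(
    log: HouseholdLog,
    visit_number: int,
    field_changes: Mapping[str, object],
    config: StudyConfig = DEFAULT_CONFIG,
) -> HouseholdLog:
    """Replace named fields of an existing visit record.

    The preload row (visit 0) is immutable. Visit number is never editable;
    the timestamp changes only if explicitly included in ``field_changes``.
    The (STATUS, DETAILS) pair is re-validated after the edit, so changing
    STATUS without supplying a compatible DETAILS fails.
    """
    if visit_number == 0:
        raise ImmutableRowError(
            f"{log.hhid}: the preload row (visit 0) cannot be edited"
        )
    if not 1 <= visit_number <= log.n_visits:
        raise NotFoundError(f"{log.hhid}: no visit {visit_number}")
    unknown = set(field_changes) - _EDITABLE_FIELDS
    if unknown:
        raise ValidationError(f"non-editable field(s): {sorted(unknown)}")

    edited = replace(log.records[visit_number], **field_changes)
    config.validate_pair(edited.status, edited.details)
    records = list(log.records)
    records[visit_number] = edited
    return replace(log, records=tuple(records))


def _terminal_visits(log: HouseholdLog, config: StudyConfig):
    return [
        rec for rec in log.visits if config.is_terminal(rec.status, rec.details)
    ]


def is_closed(log: HouseholdLog, config: StudyConfig = DEFAULT_CONFIG) -> bool:
    """True when the household requires no more visits: a terminal visit
    exists or the attempt cap is reached."""
    if _terminal_visits(log, config):
        return True
    return log.n_visits >= config.max_visits


def final_outcome(
    log: HouseholdLog, config: StudyConfig = DEFAULT_CONFIG
) -> FinalOutcome:
    """Terminal classification of a household.

    The outcome of the last terminal visit if any; NO_CONTACT when closed
    by exhausting the visit cap without a successful contact; PENDING while
    the household is still open.
    """
    terminal = _terminal_visits(log, config)
    if terminal:
        return config.outcome_of(terminal[-1].status, terminal[-1].details)
    if log.n_visits >= config.max_visits:
        return FinalOutcome.NO_CONTACT
    return FinalOutcome.PENDING
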