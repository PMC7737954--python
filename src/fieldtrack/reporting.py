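"""Campaign outcome and activity summaries.

Aggregates visit logs into the two tables a study team monitors: final
visit outcomes among households visited (counts and percentages per area
type or per community, with a TOTAL row) and overall visit activity
(scheduled vs unscheduled attempts, mean recruitment per community).

Percentages follow publication conventions: half-up rounding to 1 decimal
for outcome tables and to the nearest integer for the activity split.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .config import DEFAULT_CONFIG, StudyConfig
from .errors import ValidationError
from .model import FinalOutcome, HouseholdLog, TERMINAL_OUTCOMES
from .visit_engine import final_outcome

TOTAL_ROW = "TOTAL"


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), unlike banker's rounding."""
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    return float(
        decimal.Decimal(repr(value)).quantize(
            quantum, rounding=decimal.ROUND_HALF_UP
        )
    )


def percentage(count: int, denominator: int, ndigits: int = 1) -> float:
    """100*count/denominator rounded half-up; 0.0 when the denominator is 0."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * count / denominator, ndigits)


@dataclass(frozen=True)
class OutcomeSummary:
    """Final-outcome table: one row per group plus TOTAL.

    ``frame`` holds VISITED plus ``<OUTCOME>_N`` / ``<OUTCOME>_PCT`` column
    pairs, outcomes in publication order. ``undefined_pct_groups`` lists
    rows whose percentages are reported as 0.0 because nothing was visited.
    """

    frame: pd.DataFrame
    grouping: str
    undefined_pct_groups: tuple[str, ...] = ()

    @property
    def outcomes(self) -> tuple[FinalOutcome, ...]:
        return tuple(
            o for o in list(FinalOutcome) if f"{o.value}_N" in self.frame.columns
        )

    def row(self, group: str) -> pd.Series:
        return self.frame.loc[group]


def summary_from_counts(
    counts: Mapping[str, Mapping[FinalOutcome, int]],
    grouping: str = "area_type",
) -> OutcomeSummary:
    """Build an outcome summary from per-group outcome counts.

    ``counts`` maps group label -> {outcome: n households}. The visited
    denominator of each row is the sum of its outcome counts, and a TOTAL
    row is the element-wise sum of the groups.
    """
    present = {
        o for group_counts in counts.values() for o in group_counts
    }
    order = list(TERMINAL_OUTCOMES) + [FinalOutcome.PENDING]
    outcomes = [o for o in order if o in present] or list(TERMINAL_OUTCOMES)

    totals = {o: 0 for o in outcomes}
    rows, index, undefined = [], [], []
    for group, group_counts in counts.items():
        ns = {o: int(group_counts.get(o, 0)) for o in outcomes}
        for o in outcomes:
            totals[o] += ns[o]
        rows.append(ns)
        index.append(group)
    rows.append(totals)
    index.append(TOTAL_ROW)

    table = []
    for group, ns in zip(index, rows):
        visited = sum(ns.values())
        if visited == 0:
            undefined.append(group)
        record: dict[str, object] = {"VISITED": visited}
        for o in outcomes:
            record[f"{o.value}_N"] = ns[o]
            record[f"{o.value}_PCT"] = percentage(ns[o], visited)
        table.append(record)
    frame = pd.DataFrame(table, index=pd.Index(index, name=grouping.upper()))
    return OutcomeSummary(
        frame=frame, grouping=grouping,
        undefined_pct_groups=tuple(undefined),
    )


def summarize_outcomes(
    logs: Mapping[str, HouseholdLog] | Iterable[HouseholdLog],
    grouping: str = "area_type",
    config: StudyConfig = DEFAULT_CONFIG,
    include_pending: bool = False,
) -> OutcomeSummary:
    """Tabulate final outcomes among households visited.

    The universe is households with at least one recorded visit. Open
    (PENDING) households are excluded unless ``include_pending`` is set,
    in which case they appear as their own outcome column. Grouping is by
    ``area_type`` or ``cluster``; a TOTAL row is always appended.
    """
    if grouping not in ("area_type", "cluster"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    if isinstance(logs, Mapping):
        logs = logs.values()

    counts: dict[str, dict[FinalOutcome, int]] = {}
    for log in logs:
        if log.n_visits == 0:
            continue
        outcome = final_outcome(log, config)
        if outcome is FinalOutcome.PENDING and not include_pending:
            continue
        group = (log.area_type.value if grouping == "area_type"
                 else log.cluster)
        group_counts = counts.setdefault(
            group, {o: 0 for o in TERMINAL_OUTCOMES}
        )
        group_counts[outcome] = group_counts.get(outcome, 0) + 1
    counts = dict(sorted(counts.items()))
    if not counts:
        counts = {"(none)": {o: 0 for o in TERMINAL_OUTCOMES}}
    return summary_from_counts(counts, grouping=grouping)


@dataclass(frozen=True)
class VisitActivitySummary:
    """Overall visit-attempt statistics for a campaign."""

    total_visits: int
    scheduled: int
    unscheduled: int
    scheduled_pct: int
    unscheduled_pct: int
    recruited_households: int
    n_clusters: int
    mean_recruited_per_cluster: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def _is_scheduled(log: HouseholdLog, visit_index: int) -> bool:
    """A visit is scheduled iff an earlier record set FU_DATE to its date."""
    target = log.records[visit_index].visit_date
    if target is None:
        return False
    return any(
        rec.fu_date == target for rec in log.records[:visit_index]
    )


def summarize_activity(
    logs: Mapping[str, HouseholdLog] | Iterable[HouseholdLog],
    config: StudyConfig = DEFAULT_CONFIG,
    n_clusters: Optional[int] = None,
) -> VisitActivitySummary:
    """Totals of scheduled vs unscheduled visit attempts plus recruitment
    yield per community.

    ``n_clusters`` overrides the number of communities (by default the
    distinct cluster codes present in the logs), for campaigns where some
    communities have no visits yet.
    """
    if isinstance(logs, Mapping):
        logs = logs.values()
    logs = list(logs)

    total = scheduled = 0
    recruited = 0
    clusters = set()
    for log in logs:
        clusters.add(log.cluster)
        for idx in range(1, len(log.records)):
            total += 1
            if _is_scheduled(log, idx):
                scheduled += 1
        if final_outcome(log, config) is FinalOutcome.RECRUITED:
            recruited += 1

    unscheduled = total - scheduled
    k = n_clusters if n_clusters is not None else len(clusters)
    mean = int(round_half_up(recruited / k)) if k else 0
    return VisitActivitySummary(
        total_visits=total,
        scheduled=scheduled,
        unscheduled=unscheduled,
        scheduled_pct=int(percentage(scheduled, total, 0)),
        unscheduled_pct=int(percentage(unscheduled, total, 0)),
        recruited_households=recruited,
        n_clusters=k,
        mean_recruited_per_cluster=mean,
    )


def export_report(
    summary: OutcomeSummary | VisitActivitySummary | pd.DataFrame,
    path,
    format: str = "csv",
) -> Path:
    """Write a summary table to CSV or TSV with stable column order.

    Re-exporting the same summary is byte-identical, so reports can be
    diffed across saves.
    """
    if format not in ("csv", "tsv"):
        raise ValidationError(f"unknown format {format!r}")
    sep = "," if format == "csv" else "\t"
    if isinstance(summary, OutcomeSummary):
        frame, index = summary.frame, True
    elif isinstance(summary, VisitActivitySummary):
        frame, index = summary.to_frame(), False
    else:
        frame, index = summary, True
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        frame.to_csv(fh, sep=sep, index=index)
    return path
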