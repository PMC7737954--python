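"""Synthetic communities and campaign simulation.

Generates geocoded structures inside per-community bounding boxes and
replays a multi-visit recruitment campaign against them, driving only the
public visit-engine and marker-state APIs: each simulated field day takes
the daily worklist, attempts the households it prioritizes, honors
appointments (PINK), overdue follow-ups (RED outline) and the
Saturday-visit advisory (BLACK households are only attempted on
Saturdays), and draws each visit's result from the configured
probabilities. Everything is deterministic under the spec seed.

The default probabilities are inverted from published campaign marginals
(per-structure non-home rate, per-visit contact rate chosen so three
misses reproduce the no-contact share, and contact results split
proportionally), so a large default simulation converges to those
outcome percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional, Sequence

import numpy as np

from . import config as vocab
from .config import DEFAULT_CONFIG, StudyConfig
from .errors import ValidationError
from .marker_state import SATURDAY, daily_worklist
from .model import (
    AreaType,
    BBox,
    HouseholdLog,
    MarkerColor,
    MarkerOutline,
    Structure,
    VisitRecord,
)
from .visit_engine import is_closed, record_visit

#: Final-outcome shares the default campaign is calibrated to
#: (recruited, refused, ineligible, no-contact, not-a-home).
DEFAULT_OUTCOME_RATES = (0.097, 0.085, 0.374, 0.256, 0.188)


def _default_bboxes(n_clusters: int) -> tuple[BBox, ...]:
    """Small disjoint community boxes on a grid in a coastal study region."""
    boxes = []
    for i in range(n_clusters):
        lat0 = 17.95 + 0.03 * (i // 8)
        lon0 = -66.80 + 0.03 * (i % 8)
        boxes.append(BBox(min_lat=lat0, min_lon=lon0,
                          max_lat=lat0 + 0.02, max_lon=lon0 + 0.02))
    return tuple(boxes)


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of a synthetic recruitment campaign.

    Probabilities: ``p_not_a_home`` is drawn once per structure (a vacant
    or non-residential unit stays that way); ``p_contact`` is the per-visit
    chance somebody answers; conditional on contact, the result is
    recruited / refused / ineligible with the given probabilities and
    undecided with the remainder; an undecided resident schedules a
    follow-up 1-7 days ahead with probability ``fu_request_prob``.
    """

    n_clusters: int = 38
    structures_per_cluster: int = 627
    p_contact: float = 1.0 - (0.256 / 0.812) ** (1.0 / 3.0)
    p_recruit: float = 0.097 / 0.556
    p_refuse: float = 0.085 / 0.556
    p_ineligible: float = 0.374 / 0.556
    p_not_a_home: float = 0.188
    fu_request_prob: float = 0.25
    seed: int = 0
    cluster_bboxes: Optional[tuple[BBox, ...]] = None
    apartment_clusters: tuple[str, ...] = ()

    def __post_init__(self):
        probs = (self.p_contact, self.p_recruit, self.p_refuse,
                 self.p_ineligible, self.p_not_a_home, self.fu_request_prob)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if self.p_recruit + self.p_refuse + self.p_ineligible > 1.0 + 1e-12:
            raise ValidationError(
                "p_recruit + p_refuse + p_ineligible must be <= 1"
            )
        if self.n_clusters < 1 or self.structures_per_cluster < 1:
            raise ValidationError("need at least one cluster and structure")
        if (self.cluster_bboxes is not None
                and len(self.cluster_bboxes) != self.n_clusters):
            raise ValidationError("cluster_bboxes length must equal n_clusters")

    @property
    def p_undecided(self) -> float:
        return max(0.0, 1.0 - self.p_recruit - self.p_refuse
                   - self.p_ineligible)

    @classmethod
    def from_final_outcome_rates(
        cls,
        recruited: float,
        refused: float,
        ineligible: float,
        no_contact: float,
        not_a_home: float,
        max_visits: int = 3,
        **kwargs,
    ) -> "CampaignSpec":
        """Invert final-outcome shares into per-visit probabilities.

        Exact when undecided contacts are absent: the non-home share maps
        directly, the no-contact share equals (1 - p_contact)^max_visits
        among residential structures, and contacted households split
        proportionally to the three terminal contact outcomes.
        """
        total = recruited + refused + ineligible + no_contact + not_a_home
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"outcome rates must sum to 1, got {total:.6f}"
            )
        residential = 1.0 - not_a_home
        if residential <= 0:
            raise ValidationError("not_a_home rate must be < 1")
        p_contact = 1.0 - (no_contact / residential) ** (1.0 / max_visits)
        contacted = recruited + refused + ineligible
        return cls(
            p_contact=p_contact,
            p_recruit=recruited / contacted,
            p_refuse=refused / contacted,
            p_ineligible=ineligible / contacted,
            p_not_a_home=not_a_home,
            **kwargs,
        )


DEFAULT_CAMPAIGN = CampaignSpec()


def logs_from_outcome_counts(
    counts_by_area: dict[AreaType, dict],
    config: StudyConfig = DEFAULT_CONFIG,
    start_date: date = date(2018, 4, 2),
) -> dict[str, HouseholdLog]:
    """Engineer a log collection whose final outcomes match given counts.

    ``counts_by_area`` maps an area type to ``{FinalOutcome: n households}``.
    Useful for reproducing a published outcome table exactly: summarizing
    the returned logs recovers the input counts. NO_CONTACT households get
    ``max_visits`` no-answer attempts (the last on a Saturday); every other
    outcome closes with a single terminal visit.
    """
    from .model import FinalOutcome

    monday = start_date
    saturday = start_date + timedelta(days=(SATURDAY - start_date.isoweekday()) % 7)
    visit_plan = {
        FinalOutcome.RECRUITED: [(vocab.CONTACT_MADE, vocab.RECRUITED, monday)],
        FinalOutcome.REFUSED: [(vocab.CONTACT_MADE, vocab.REFUSED, monday)],
        FinalOutcome.INELIGIBLE: [
            (vocab.CONTACT_MADE, vocab.INELIGIBLE, monday)
        ],
        FinalOutcome.NOT_A_HOME: [(vocab.VACANT, "EMPTY_HOME", monday)],
        FinalOutcome.NO_CONTACT: (
            [(vocab.NO_ANSWER, "NO_ONE_HOME",
              monday + timedelta(days=i)) for i in range(config.max_visits - 1)]
            + [(vocab.NO_ANSWER, "NO_ONE_HOME", saturday)]
        ),
    }
    logs: dict[str, HouseholdLog] = {}
    ref = 0
    for area, outcome_counts in counts_by_area.items():
        cluster = f"X{area.value[:2]}"
        for outcome, n in outcome_counts.items():
            plan = visit_plan[outcome]
            for i in range(int(n)):
                hhid = f"{cluster}-{outcome.value[:3]}-{i:05d}"
                records = [VisitRecord(ref=ref, hhid=hhid, cluster=cluster,
                                       lon=-66.6, lat=18.0, visit=0)]
                for v, (status, details, day) in enumerate(plan, start=1):
                    records.append(VisitRecord(
                        ref=ref, hhid=hhid, cluster=cluster, lon=-66.6,
                        lat=18.0, visit=v, structure="HOUSE", status=status,
                        details=details,
                        visit_datetime=datetime.combine(day, time(9, 0)),
                        initials="EN",
                    ))
                logs[hhid] = HouseholdLog(
                    hhid=hhid, records=tuple(records), area_type=area
                )
                ref += 1
    return logs


def logs_with_visit_mix(
    n_scheduled: int,
    n_unscheduled: int,
    n_clusters: int = 1,
    start_date: date = date(2018, 4, 2),
) -> dict[str, HouseholdLog]:
    """Engineer logs containing exact scheduled/unscheduled visit totals.

    A scheduled visit is one whose date was set as FU_DATE by an earlier
    record of the same household. Each scheduled visit is realized as a
    two-visit household (an unscheduled contact that books a follow-up,
    then the kept appointment), so ``n_unscheduled`` must be at least
    ``n_scheduled``; the remainder are single-visit households.
    """
    if n_unscheduled < n_scheduled:
        raise ValidationError(
            "each scheduled visit is preceded by an unscheduled one: "
            "n_unscheduled must be >= n_scheduled"
        )
    day1, day2 = start_date, start_date + timedelta(days=1)
    logs: dict[str, HouseholdLog] = {}

    def _mk(hhid, cluster, visits):
        records = [VisitRecord(ref=0, hhid=hhid, cluster=cluster,
                               lon=-66.6, lat=18.0, visit=0)]
        for v, (status, details, day, fu) in enumerate(visits, start=1):
            records.append(VisitRecord(
                ref=0, hhid=hhid, cluster=cluster, lon=-66.6, lat=18.0,
                visit=v, structure="HOUSE", status=status, details=details,
                visit_datetime=datetime.combine(day, time(9, 0)),
                fu_date=fu, initials="EN",
            ))
        return HouseholdLog(hhid=hhid, records=tuple(records))

    for i in range(n_scheduled):
        cluster = f"C{i % n_clusters:02d}"
        hhid = f"SCH-{i:05d}"
        logs[hhid] = _mk(hhid, cluster, [
            (vocab.CONTACT_MADE, vocab.UNDECIDED, day1, day2),
            (vocab.CONTACT_MADE, vocab.UNDECIDED, day2, None),
        ])
    for i in range(n_unscheduled - n_scheduled):
        cluster = f"C{i % n_clusters:02d}"
        hhid = f"UNS-{i:05d}"
        logs[hhid] = _mk(
            hhid, cluster,
            [(vocab.NO_ANSWER, "NO_ONE_HOME", day1, None)],
        )
    return logs


def generate_communities(spec: CampaignSpec) -> list[Structure]:
    """Scatter structures uniformly inside each community bounding box.

    HHIDs are ``<cluster>-<serial>``; clusters are ``C01..``; coordinates
    are reproducible under ``spec.seed``.
    """
    bboxes = spec.cluster_bboxes or _default_bboxes(spec.n_clusters)
    for box in bboxes:
        if box.min_lat == box.max_lat or box.min_lon == box.max_lon:
            raise ValidationError(f"degenerate community bbox: {box}")
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    structures = []
    for ci, box in enumerate(bboxes):
        cluster = f"C{ci + 1:02d}"
        area = (AreaType.APARTMENT if cluster in spec.apartment_clusters
                else AreaType.NEIGHBORHOOD)
        lats = rng.uniform(box.min_lat, box.max_lat,
                           spec.structures_per_cluster)
        lons = rng.uniform(box.min_lon, box.max_lon,
                           spec.structures_per_cluster)
        structures.extend(
            Structure(
                hhid=f"{cluster}-{i + 1:04d}",
                cluster=cluster,
                lat=float(lats[i]),
                lon=float(lons[i]),
                area_type=area,
            )
            for i in range(spec.structures_per_cluster)
        )
    return structures


def _next_field_day(day: date) -> date:
    day = day + timedelta(days=1)
    if day.isoweekday() == 7:  # Sunday: no field work
        day += timedelta(days=1)
    return day


def _draw_entry(spec: CampaignSpec, rng, not_a_home: bool, day: date):
    """One visit result: (status, details, fu_offset_days or None)."""
    if not_a_home:
        if rng.random() < 0.5:
            return vocab.NOT_A_HOME, "NON_RESIDENTIAL", None
        return vocab.VACANT, "EMPTY_HOME", None
    if rng.random() >= spec.p_contact:
        return vocab.NO_ANSWER, "NO_ONE_HOME", None
    u = rng.random()
    if u < spec.p_recruit:
        return vocab.CONTACT_MADE, vocab.RECRUITED, None
    if u < spec.p_recruit + spec.p_refuse:
        return vocab.CONTACT_MADE, vocab.REFUSED, None
    if u < spec.p_recruit + spec.p_refuse + spec.p_ineligible:
        return vocab.CONTACT_MADE, vocab.INELIGIBLE, None
    fu_offset = None
    if rng.random() < spec.fu_request_prob:
        fu_offset = int(rng.integers(1, 8))
    return vocab.CONTACT_MADE, vocab.UNDECIDED, fu_offset


def _should_attempt(state, today: date) -> bool:
    if state.base is MarkerColor.PINK:
        return True
    if state.outline is MarkerOutline.RED_OUTLINE:
        return True
    if state.base is MarkerColor.BLACK:
        return today.isoweekday() == SATURDAY
    if state.base is MarkerColor.GREY:
        return False  # wait for the appointment day
    return state.base in (MarkerColor.BLUE, MarkerColor.ORANGE)


def simulate_campaign(
    structures: Sequence[Structure],
    spec: CampaignSpec,
    config: StudyConfig = DEFAULT_CONFIG,
    start_date: date = date(2018, 4, 2),
    max_days: int = 730,
) -> dict[str, HouseholdLog]:
    """Replay a full campaign; every log is built through ``record_visit``.

    Field days run Monday-Saturday. Each day the worklist is walked in
    priority order and every household the field policy selects (see
    :func:`_should_attempt`) receives one attempt whose result is drawn
    from the spec probabilities. The campaign ends when every household is
    closed (or after ``max_days`` as a safety stop).
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    logs = {
        s.hhid: HouseholdLog.from_structure(s, ref=i)
        for i, s in enumerate(structures)
    }
    non_home = {
        s.hhid: bool(rng.random() < spec.p_not_a_home) for s in structures
    }

    day = start_date
    if day.isoweekday() == 7:
        day = _next_field_day(day)
    open_ids = set(logs)
    for _ in range(max_days):
        if not open_ids:
            break
        worklist = daily_worklist(
            {h: logs[h] for h in open_ids}, day, config
        )
        serial = 0
        for hhid, state in worklist:
            if not _should_attempt(state, day):
                continue
            status, details, fu_offset = _draw_entry(
                spec, rng, non_home[hhid], day
            )
            fu_date = None
            if fu_offset is not None:
                fu_date = day + timedelta(days=fu_offset)
                if fu_date.isoweekday() == 7:
                    fu_date += timedelta(days=1)
            # visits stay inside an 8:00-18:00 window whatever the volume
            now = datetime.combine(day, time(8, 0)) + timedelta(
                seconds=serial % 36_000
            )
            serial += 1
            logs[hhid] = record_visit(
                logs[hhid],
                {
                    "structure": "HOUSE",
                    "status": status,
                    "details": details,
                    "fu_date": fu_date,
                    "initials": "SIM",
                },
                now=now,
                config=config,
            )
            if is_closed(logs[hhid], config):
                open_ids.discard(hhid)
        day = _next_field_day(day)
    return logs
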